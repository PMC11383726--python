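# Methods

This note documents the statistical model, the numerical choices, and
what the synthetic-data validation does and does not establish.

## The two-sample MR model

Each instrument j contributes summary associations
(β̂_Xj, se_Xj) with the exposure and (β̂_Yj, se_Yj) with the outcome,
measured in non-overlapping samples. Under the instrumental-variable
assumptions (relevance, no confounding of the instrument, exclusion
restriction) each Wald ratio β̂_Yj/β̂_Xj estimates the same causal effect
β. The estimators differ in how they defend that assumption set:

- **IVW** assumes all instruments valid; it is the minimum-variance
  combination of the ratios and the primary decision criterion
  throughout (secondary estimators never gate a screen flag).
- **MR-Egger** relaxes exclusion to the InSIDE condition (instrument
  strength independent of direct effects): directional pleiotropy is
  absorbed by the intercept and the slope remains consistent. Exposure
  effects are oriented non-negative before the fit, as the intercept is
  only defined relative to an orientation.
- **Weighted median** is consistent when instruments carrying at least
  half the total weight are valid.
- **Mode-based estimators** are consistent when the largest homogeneous
  cluster of ratios is valid (ZEMPA).

Binary-trait effects are log-odds everywhere; `to_odds_ratio` applies
exp() and 1.96-SE normal bounds only at reporting time, matching how
such studies print OR (95% CI).

## Instrument selection

Defaults: p < 1e-5, clump window 10,000 kb, clump r² ≤ 0.001, F > 10.
The variance explained by a SNP is R² = 2·EAF·(1−EAF)·β² (β on a
standardized-trait scale) and F = R²(n−2)/(1−R²), computed per SNP, not
as a mean-F. Clumping is greedy on ascending p-value with lexical snp_id
tie-breaks, so output never depends on input row order. Without an LD
matrix, SNPs sharing a locus are treated as perfectly correlated and
distinct loci as independent — a fallback only; the synthetic generator
always emits an LD matrix.

## Numerical and inferential choices

- IVW weights are first-order (1/se_Y²); second-order weights were
  rejected to match prevailing defaults.
- Random-effects fallback: when Cochran's Q (k−1 df) has p < q_alpha
  (default .05), the IVW SE is multiplied by √max(1, Q/(k−1)). The same
  floor-at-1 multiplicative scale is used for the MR-Egger coefficient
  covariance, so random-effects never deflate below the fixed-effect SE.
- MR-Egger p-values use Student t with k−2 df; all other estimators use
  the normal. k ≥ 3 is required for Egger/median/mode; k = 1 reduces to
  the Wald ratio.
- Weighted-median and mode SEs come from a parametric bootstrap
  (resampling both effect columns from their normals, default 1000
  draws). Seeds are mandatory arguments; there is no hidden global RNG.
  Analytic median SEs were not implemented; the bootstrap choice is
  documented as a deliberate default.
- Mode bandwidth: phi × 0.9·min(sd, MAD)/k^(1/5), density maximized on a
  1024-point grid spanning the ratios ± 3 bandwidths; identical ratios
  short-circuit to the heaviest point.
- Harmonization resolves palindromic (A/T, G/C) SNPs by allele frequency
  only when both EAFs are outside 0.5 ± 0.08 (window configurable);
  otherwise the SNP is dropped with reason `palindromic-ambiguous`.
  The p-vs-|β/se| consistency check warns rather than drops, because
  published tables round.
- MR-PRESSO follows the published algorithm: leave-one-out IVW expected
  values, parametric simulation of both effect columns (default 1000
  draws), add-one Monte-Carlo p-values (never exactly zero), per-SNP
  outlier flags at sig/k (Bonferroni), one outlier-removed re-estimate
  (no iteration), and a random-subset distortion null. Note the flag
  threshold is unreachable when n_sim + 1 ≤ k/sig; the code warns.
- Mediation CIs default to the delta method (Sobel), which reproduces
  the published worked examples' symmetric intervals; a seeded
  product-of-normals Monte-Carlo interval is available. The proportion
  mediated is reported on the log-odds scale and is undefined (NaN) when
  the total effect is zero.
- Screens apply no multiple-testing correction to the positive flag
  (raw p < .05 on IVW, as the emulated study design does); a
  Benjamini–Hochberg FDR column is emitted for information only.

## The synthetic-data generator

`simulate_pair` draws, per SNP: EAF ~ U(0.05, 0.95); a true exposure
effect |β_X| ~ U(0.12, 0.7) with effect alleles oriented
trait-increasing; observed β̂_X ~ N(β_X, se_X) with
se_X = 1/√(2·EAF·(1−EAF)·n_exp); and an outcome effect
β_Y = β·β_X + α_j plus noise at se_Y, where se_Y additionally carries a
1/√(φ(1−φ)) inflation for a binary outcome with case fraction φ. The
pleiotropy term α_j is zero (`none`), N(0, sd) (`balanced`) or
N(mean, sd) (`directional`); `inside_violation` couples it to centred
instrument strength. LD matrices are block-diagonal with configurable
within-block r²; independent loci are spaced beyond the clump window.

Default conditions mirror the emulated study where published: exposure
panel n = 14,824 (cytokines), mediator panel n = 8,299 (metabolites),
effect-size range chosen so per-SNP F spans roughly 20–3500, the
published instrument-strength range. The outcome is scaled down: the
real outcome's extreme imbalance (157 cases in ~408k) yields per-SNP SEs
too large for any desk-scale simulation to have power, so defaults use
n_out = 50,000 with case fraction 0.1, keeping the same SE structure at
a workable scale. Replicate counts in the validation suite (200 for
recovery means, 100 panels for calibration, 50 for outlier detection)
were chosen to give Monte-Carlo SEs well below the effects being
measured.

The trait-increasing orientation of exposure effect alleles mirrors the
reporting convention of cytokine/metabolite panels and makes
"directional" pleiotropy directional *on a fixed orientation* — the
regime in which the Egger intercept is an estimand. Had signs been
random, orientation inside Egger would fold directional effects into
balanced ones.

What the generator does **not** model: realistic LD from reference
panels, winner's curse in instrument discovery, sample overlap between
the two samples, allele-frequency differences between studies, and
individual-level binary-trait likelihoods (effects are generated
directly on the log-odds scale). Passing tests therefore demonstrate
correctness of the estimators and pipeline under the stated generative
model, not robustness to those real-data complications.

## Mediation: two-step MR

β₁ (exposure→mediator) and β₂ (mediator→outcome) are IVW estimates on
their own instrument sets; the screen keeps mediators with both step
p-values < .05, then reports indirect = β₁β₂, direct = β_all − β₁β₂
and proportion = β₁β₂/β_all against the total IVW estimate β_all. The
decomposition identity direct + indirect = β_all holds by construction
and is asserted in the report. On a binary outcome this identity is an
approximation inherited from working on the log-odds scale (as the
emulated design does); no rare-disease correction is applied.

## Known limitations

- Steiger directionality filtering and multivariable MR are out of
  scope; as the bidirectional tests show, a strong causal trait's
  instruments can echo as a spurious reverse signal when the outcome's
  instrument set overlaps them.
- No correction is applied for the extremely unbalanced binary outcome
  beyond the standard log-odds treatment.
- The reverse direction uses a binary trait's log-odds betas as exposure
  effects unchanged (estimates are then per log-odds unit); this is
  logged as a caveat at run time.
- Indels, multi-allelic variants, GWAS-VCF input and liftover are not
  supported.
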