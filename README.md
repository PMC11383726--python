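# mrlink

Two-sample Mendelian randomization (MR) and two-step mediation MR on GWAS
summary statistics, built for panel-scale screens such as circulating
inflammatory cytokines against hepatic fibrosis with blood metabolites as
candidate mediators.

## What it does

Given per-SNP association tables (effect allele, EAF, β, SE, p, N) for an
exposure and an outcome, `mrlink`:

1. **selects instruments** — p < 1e-5, greedy LD clumping (10 Mb window,
   r² ≤ 0.001), and per-SNP strength filtering with
   R² = 2·EAF·(1−EAF)·β² and F = R²(n−2)/(1−R²), keeping F > 10;
2. **harmonizes** exposure and outcome effects onto a shared
   effect-allele orientation (swapped, complementary-strand, and
   EAF-resolved palindromic variants; ambiguous palindromes dropped);
3. **estimates the causal effect** five ways. With Wald ratios
   β̂ⱼ = β_Yⱼ/β_Xⱼ and weights wⱼ = (β_Xⱼ/se_Yⱼ)²:
   - **IVW** (primary): β̂ = Σwⱼβ̂ⱼ / Σwⱼ, equal to weighted least squares
     of β_Y on β_X through the origin; if Cochran's
     Q = Σwⱼ(β̂ⱼ − β̂)² is significant the SE is inflated by
     √max(1, Q/(k−1)) (multiplicative random effects);
   - **MR-Egger**: the same regression with an intercept; a non-null
     intercept indicates directional pleiotropy;
   - **weighted median**: the weight-0.5 quantile of the ordered ratios;
   - **weighted and simple mode**: the maximizer of a kernel-smoothed
     ratio density (bootstrap SEs, seeded);
4. **runs the sensitivity battery** — Cochran's Q, the Egger intercept
   test, MR-PRESSO (global, per-SNP outlier, and distortion tests with a
   single outlier-corrected re-estimate), leave-one-out, and
   scatter/funnel plot-data export;
5. **decomposes mediation** in two-step MR: exposure→mediator (β₁),
   mediator→outcome (β₂), exposure→outcome total (β_all); the indirect
   effect is β₁β₂ with Sobel SE √(β₁²se₂² + β₂²se₁²), the direct effect
   β_all − β₁β₂, and the proportion mediated β₁β₂/β_all.

Binary outcomes are handled on the log-odds scale throughout; odds ratios
and 1.96-SE CIs appear only in reports. A synthetic-data module generates
summary statistics with known causal structure (configurable true
effects, pleiotropy, LD blocks, rare-outcome SE inflation) so every stage
is testable offline.

## Worked example

```python
from mrlink import MRModel, SimulationTruth, simulate_pair

truth = SimulationTruth(seed=7, k_snps=30, beta_xy=0.5)   # known truth
exposure, outcome, ld = simulate_pair(truth)
model = MRModel.from_tables(exposure, outcome, ld=ld)
res = model.fit(seed=11)
print(res.summary())
presso = res.run_presso(n_sim=1000, seed=13)
print(f"MR-PRESSO global p = {presso.global_pval:.3f}, "
      f"outliers flagged: {len(presso.outliers)}")
```

```
Two-sample Mendelian randomization
======================================================================
Exposure: synthetic_exposure
Outcome:  synthetic_outcome
Instruments (after harmonization): 30
----------------------------------------------------------------------
method                                        beta     se       p
Inverse variance weighted (fixed effects)    0.490  0.011       0
                                          OR 1.632 (95% CI 1.598-1.666)
MR Egger                                     0.540  0.0292.04e-17
                                          OR 1.716 (95% CI 1.622-1.815)
Weighted median                              0.497  0.0162.17e-217
                                          OR 1.643 (95% CI 1.593-1.695)
Weighted mode                                0.493  0.0192.16e-145
                                          OR 1.638 (95% CI 1.577-1.700)
Simple mode                                  0.507  0.0246.18e-103
                                          OR 1.660 (95% CI 1.585-1.739)
----------------------------------------------------------------------
Cochran's Q = 26.403 (df 29, p = 0.604)
Egger intercept = -0.0230 (se 0.0122, p = 0.0706)
MR-PRESSO global p = 0.717, outliers flagged: 0
```

All five estimators recover the simulated causal effect of 0.5; the
diagnostics correctly find no heterogeneity (Q p = 0.60), no directional
pleiotropy (intercept p = 0.07) and no outliers — as they should on data
generated without either.

The same machinery is available from the shell:

```bash
mrlink simulate --seed 7 --out data --k-snps 30 --beta-xy 0.5
mrlink mr --exposure data/exposure.tsv --outcome data/outcome.tsv \
          --ld data/ld.tsv --seed 11 --out results
mrlink screen ... ; mrlink bidirectional ... ; mrlink mediate ...
```

Readers for FinnGen-style and GWAS-Catalog-style headers are built in
(`--format finngen`, `--format gwas-catalog`).

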