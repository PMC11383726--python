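"""Synthetic GWAS summary statistics with known causal structure.

The generator emits summary tables shaped like the real inputs the
package targets — a continuous exposure panel (cytokine-like, default
n = 14,824), a mediator panel (metabolite-like, default n = 8,299) and a
binary outcome on the log-odds scale with a configurable case fraction —
without ever touching individual-level genotypes: observed effects are
drawn from normals centred on the true per-SNP effects, with standard
errors at the 1/sqrt(2 p (1-p) n) scale so that the F-statistic and
variance-explained formulas behave as they do on real data. Binary
outcomes inflate the SE by 1/sqrt(phi (1-phi)) for case fraction phi,
a reduced-scale emulation of heavily imbalanced biobank outcomes.

Exposure effect alleles are oriented trait-increasing (true instrument
effects are positive), matching the reporting convention of cytokine and
metabolite GWAS panels; directional pleiotropy is therefore expressed on
a fixed orientation and is recoverable as an MR-Egger intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .gwas_io import SummaryStatTable, SummaryStatRecord

__all__ = [
    "SimulationTruth",
    "simulate_pair",
    "simulate_mediation_triple",
    "make_fixture_panel",
]

# non-palindromic allele pairs only, so harmonization never drops a SNP
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

#: base-pair gap between independent loci; larger than the default 10 Mb
#: clumping window so distinct instruments are never co-clumped
_LOCUS_SPACING = 25_000_000


@dataclass
class SimulationTruth:
    """Generating parameters for one synthetic dataset.

    ``beta_xy`` is the true exposure -> outcome causal effect (direct, on
    top of any mediated path); ``beta_xm``/``beta_my`` the mediation-path
    effects. ``pleiotropy`` adds per-SNP direct effects on the outcome:
    ``balanced`` draws them around zero, ``directional`` around
    ``pleio_mean``. ``inside_violation`` correlates those direct effects
    with instrument strength, breaking the InSIDE condition.
    """

    seed: int
    k_snps: int = 50
    beta_xy: float = 0.0
    beta_xm: float = 0.0
    beta_my: float = 0.0
    pleiotropy: str = "none"  # none | balanced | directional
    pleio_mean: float = 0.05
    pleio_sd: float = 0.02
    inside_violation: bool = False
    n_exp: int = 14_824
    n_out: int = 50_000
    n_med: int = 8_299
    case_fraction: float = 0.1
    outcome_binary: bool = True
    ld_blocks: list[tuple[int, float]] | None = None  # (block size, within-block r2)
    maf_range: tuple[float, float] = (0.05, 0.95)
    effect_range: tuple[float, float] = (0.12, 0.7)

    def __post_init__(self) -> None:
        if self.k_snps < 4:
            raise InputError("k_snps must be at least 4")
        if min(self.n_exp, self.n_out, self.n_med) < 100:
            raise InputError("sample sizes must be at least 100")
        if not (0.0 < self.case_fraction <= 0.5):
            raise InputError("case_fraction must be in (0, 0.5]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise InputError(f"unknown pleiotropy kind {self.pleiotropy!r}")
        if self.ld_blocks is not None and sum(b for b, _ in self.ld_blocks) != self.k_snps:
            raise InputError("ld_blocks sizes must sum to k_snps")

    def to_frame(self) -> pd.DataFrame:
        d = asdict(self)
        d["ld_blocks"] = repr(self.ld_blocks)
        return pd.DataFrame([d])


def _se_scale(eaf: np.ndarray, n: float, case_fraction: float | None = None) -> np.ndarray:
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)
    if case_fraction is not None:
        se = se / np.sqrt(case_fraction * (1.0 - case_fraction))
    return se


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _layout(truth: SimulationTruth, rng: np.random.Generator, prefix: str = "rs",
            locus_offset: float = 0.0):
    """SNP ids, loci, alleles, EAFs and the LD matrix skeleton."""
    k = truth.k_snps
    ids = [f"{prefix}{i + 1:06d}" for i in range(k)]
    blocks = truth.ld_blocks or [(1, 0.0)] * k
    loci = np.empty(k)
    ld = np.eye(k)
    pos = 0
    base = 1_000_000 + locus_offset
    for size, r2 in blocks:
        sl = slice(pos, pos + size)
        loci[sl] = base + np.arange(size) * 10_000  # within-block: 10 kb apart
        ld[sl, sl] = np.where(np.eye(size, dtype=bool), 1.0, r2)
        base += _LOCUS_SPACING
        pos += size
    eaf = rng.uniform(*truth.maf_range, size=k)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    alleles = [_ALLELE_PAIRS[i] for i in allele_idx]
    ld_frame = pd.DataFrame(ld, index=ids, columns=ids)
    return ids, loci, alleles, eaf, ld_frame


def _table(name, trait_type, ids, alleles, eaf, beta, se, n, loci) -> SummaryStatTable:
    pvals = _pvals(beta, se)
    records = [
        SummaryStatRecord(
            snp_id=ids[j],
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            eaf=float(eaf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(pvals[j]),
            n=float(n),
            locus=float(loci[j]),
        )
        for j in range(len(ids))
    ]
    return SummaryStatTable(name, trait_type, records)


def _direct_effects(truth: SimulationTruth, rng: np.random.Generator, b_x: np.ndarray) -> np.ndarray:
    k = truth.k_snps
    if truth.pleiotropy == "none":
        alpha = np.zeros(k)
    elif truth.pleiotropy == "balanced":
        alpha = rng.normal(0.0, truth.pleio_sd, size=k)
    else:
        alpha = rng.normal(truth.pleio_mean, truth.pleio_sd, size=k)
    if truth.inside_violation:
        strength = b_x - b_x.mean()
        alpha = alpha + 0.5 * strength  # couples direct effects to instrument strength
    return alpha


def simulate_pair(
    truth: SimulationTruth,
    exposure_name: str = "synthetic_exposure",
    outcome_name: str = "synthetic_outcome",
    snp_prefix: str = "rs",
    locus_offset: float = 0.0,
) -> tuple[SummaryStatTable, SummaryStatTable, pd.DataFrame]:
    """One exposure-outcome pair with known causal effect ``beta_xy``.

    Returns validated exposure and outcome tables plus the block-diagonal
    LD r^2 matrix. Same seed, same bytes.
    """
    rng = np.random.default_rng(truth.seed)
    ids, loci, alleles, eaf, ld = _layout(truth, rng, prefix=snp_prefix,
                                          locus_offset=locus_offset)
    b_x = rng.uniform(*truth.effect_range, size=truth.k_snps)
    alpha = _direct_effects(truth, rng, b_x)
    b_y = truth.beta_xy * b_x + alpha

    se_x = _se_scale(eaf, truth.n_exp)
    bhat_x = rng.normal(b_x, se_x)
    cf = truth.case_fraction if truth.outcome_binary else None
    se_y = _se_scale(eaf, truth.n_out, cf)
    bhat_y = rng.normal(b_y, se_y)

    exposure = _table(exposure_name, "continuous", ids, alleles, eaf, bhat_x, se_x, truth.n_exp, loci)
    outcome_type = "binary" if truth.outcome_binary else "continuous"
    outcome = _table(outcome_name, outcome_type, ids, alleles, eaf, bhat_y, se_y, truth.n_out, loci)
    return exposure, outcome, ld


def simulate_mediation_triple(
    truth: SimulationTruth,
    exposure_name: str = "synthetic_exposure",
    mediator_name: str = "synthetic_mediator",
    outcome_name: str = "synthetic_outcome",
    k_mediator_snps: int | None = None,
) -> tuple[SummaryStatTable, SummaryStatTable, SummaryStatTable, pd.DataFrame]:
    """Exposure, mediator and outcome tables with a known mediated path.

    The exposure's ``k_snps`` instruments carry through to the mediator
    scaled by ``beta_xm`` and to the outcome via both the direct path
    ``beta_xy`` and the mediated path ``beta_xm * beta_my``; a further
    ``k_mediator_snps`` mediator-specific instruments (null on the
    exposure) drive the mediator and reach the outcome scaled by
    ``beta_my``. The total exposure -> outcome effect is therefore
    ``beta_xy + beta_xm * beta_my`` and the indirect effect
    ``beta_xm * beta_my``.
    """
    if truth.ld_blocks is not None:
        raise InputError("ld_blocks are not supported for mediation triples")
    rng = np.random.default_rng(truth.seed)
    k_e = truth.k_snps
    k_m = k_mediator_snps if k_mediator_snps is not None else k_e
    k = k_e + k_m

    wide = SimulationTruth(seed=truth.seed, k_snps=k, n_exp=truth.n_exp,
                           n_out=truth.n_out, n_med=truth.n_med,
                           case_fraction=truth.case_fraction,
                           outcome_binary=truth.outcome_binary,
                           maf_range=truth.maf_range, effect_range=truth.effect_range)
    ids, loci, alleles, eaf, ld = _layout(wide, rng)

    effects = rng.uniform(*truth.effect_range, size=k)
    alpha = _direct_effects(truth, rng, effects[:k_e])
    b_x = np.zeros(k)
    b_x[:k_e] = effects[:k_e]
    b_m = truth.beta_xm * b_x
    b_m[k_e:] = effects[k_e:]  # mediator-specific instruments
    b_y = truth.beta_xy * b_x + truth.beta_my * b_m
    b_y[:k_e] += alpha

    se_x = _se_scale(eaf, truth.n_exp)
    se_m = _se_scale(eaf, truth.n_med)
    cf = truth.case_fraction if truth.outcome_binary else None
    se_y = _se_scale(eaf, truth.n_out, cf)
    bhat_x = rng.normal(b_x, se_x)
    bhat_m = rng.normal(b_m, se_m)
    bhat_y = rng.normal(b_y, se_y)

    exposure = _table(exposure_name, "continuous", ids, alleles, eaf, bhat_x, se_x, truth.n_exp, loci)
    mediator = _table(mediator_name, "continuous", ids, alleles, eaf, bhat_m, se_m, truth.n_med, loci)
    outcome_type = "binary" if truth.outcome_binary else "continuous"
    outcome = _table(outcome_name, outcome_type, ids, alleles, eaf, bhat_y, se_y, truth.n_out, loci)
    return exposure, mediator, outcome, ld


def make_fixture_panel(
    n_traits: int,
    n_true: int,
    seed: int,
    k_snps_per_trait: int = 20,
    beta_true: float = 0.5,
    n_exp: int = 14_824,
    n_out: int = 50_000,
    case_fraction: float = 0.1,
) -> tuple[dict[str, SummaryStatTable], SummaryStatTable, pd.DataFrame, pd.DataFrame]:
    """A multi-trait exposure panel sharing one binary outcome.

    A reduced-scale stand-in for a cytokine panel screen: each trait gets
    its own disjoint instrument block, the first ``n_true`` traits carry a
    true causal effect ``beta_true`` on the shared outcome, the rest are
    null. Returns (exposure tables by name, outcome table, LD matrix,
    truth ledger).
    """
    if n_true > n_traits:
        raise InputError("n_true cannot exceed n_traits")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_traits)]
    exposures: dict[str, SummaryStatTable] = {}
    outcome_records = []
    ld_frames = []
    truth_rows = []
    for t in range(n_traits):
        name = f"trait_{t + 1:03d}"
        causal = beta_true if t < n_true else 0.0
        truth = SimulationTruth(
            seed=child_seeds[t], k_snps=k_snps_per_trait, beta_xy=causal,
            n_exp=n_exp, n_out=n_out, case_fraction=case_fraction,
        )
        exp, out, ld = simulate_pair(
            truth, exposure_name=name, snp_prefix=f"rs{t + 1:03d}_",
            locus_offset=t * k_snps_per_trait * _LOCUS_SPACING,
        )
        exposures[name] = exp
        outcome_records.extend(out.records)
        ld_frames.append(ld)
        truth_rows.append({"trait": name, "beta_xy": causal, "seed": child_seeds[t]})
    outcome = SummaryStatTable("synthetic_outcome", "binary", outcome_records)
    ld_all = _block_diag(ld_frames)
    return exposures, outcome, ld_all, pd.DataFrame(truth_rows)


def _block_diag(frames: list[pd.DataFrame]) -> pd.DataFrame:
    ids = [i for f in frames for i in f.index]
    out = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for f in frames:
        out.loc[f.index, f.columns] = f.values
    return out
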