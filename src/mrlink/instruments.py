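"""Instrument selection: p-value threshold, greedy LD clumping, strength filters.

Instrument strength follows the usual summary-data conventions: the
variance in the exposure explained by one SNP is

    R^2 = 2 * EAF * (1 - EAF) * beta^2

(beta on a standardized-trait scale), and its F-statistic is

    F = R^2 * (n - 2) / (1 - R^2),

with F > 10 the conventional weak-instrument cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError, NoInstrumentsError
from .gwas_io import SummaryStatTable

__all__ = [
    "ClumpConfig",
    "InstrumentSet",
    "compute_r2_f",
    "clump",
    "read_ld_matrix",
    "write_ld_matrix",
]


@dataclass(frozen=True)
class ClumpConfig:
    """Selection thresholds: p < p_threshold, pairwise r^2 <= clump_r2 within
    clump_kb, and per-SNP F > f_min."""

    p_threshold: float = 1e-5
    clump_kb: float = 10_000.0
    clump_r2: float = 0.001
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise InputError("p_threshold must be in (0,1)")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise InputError("clump_r2 must be in [0,1]")
        if not (self.clump_kb > 0):
            raise InputError("clump_kb must be positive")


@dataclass
class InstrumentSet:
    """Independent, strong instruments for one exposure."""

    exposure_name: str
    table: SummaryStatTable
    per_snp_r2: dict[str, float] = field(default_factory=dict)
    per_snp_f: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.table]

    def to_frame(self) -> pd.DataFrame:
        frame = self.table.to_frame()
        frame["r2"] = [self.per_snp_r2[s] for s in frame["snp"]]
        frame["F"] = [self.per_snp_f[s] for s in frame["snp"]]
        return frame

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def compute_r2_f(beta: float, eaf: float, n: float) -> tuple[float, float]:
    """Per-SNP variance explained and F-statistic.

    Raises :class:`InputError` when R^2 >= 1, which signals a beta that is
    not on a standardized-trait scale.
    """
    if not (0.0 < eaf < 1.0):
        raise InputError("eaf must be in (0,1)")
    if n <= 2:
        raise InputError("n must exceed 2")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta * beta
    if r2 >= 1.0:
        raise InputError(f"R^2 = {r2:.3g} >= 1; beta inconsistent with standardized scale")
    f = r2 * (n - 2.0) / (1.0 - r2)
    return r2, f


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a square tab-delimited r^2 matrix with snp_id header row/column."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    ld.index = ld.index.astype(str)
    ld.columns = ld.columns.astype(str)
    return ld


def write_ld_matrix(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t")


def _check_ld(ld: pd.DataFrame, snp_ids: list[str]) -> None:
    missing = [s for s in snp_ids if s not in ld.index or s not in ld.columns]
    if missing:
        raise InputError(f"LD matrix does not cover SNPs: {missing[:5]}")
    sub = ld.loc[snp_ids, snp_ids].to_numpy(float)
    if not np.allclose(sub, sub.T, atol=1e-8):
        raise InputError("LD matrix is not symmetric")
    if not np.allclose(np.diag(sub), 1.0, atol=1e-8):
        raise InputError("LD matrix diagonal must be 1")


def _pairwise_r2(a, b, ld: pd.DataFrame | None) -> float:
    # fallback when no LD panel: same locus => perfect LD, different => none
    if ld is not None:
        return float(ld.at[a.snp_id, b.snp_id])
    la, lb = a.numeric_locus(), b.numeric_locus()
    same = (a.locus == b.locus) if (la is None or lb is None) else (la == lb)
    return 1.0 if same else 0.0


def _within_window(a, b, clump_kb: float) -> bool:
    la, lb = a.numeric_locus(), b.numeric_locus()
    if la is None or lb is None:
        return a.locus == b.locus
    return abs(la - lb) <= clump_kb * 1000.0


def clump(
    table: SummaryStatTable,
    config: ClumpConfig = ClumpConfig(),
    ld: pd.DataFrame | None = None,
) -> InstrumentSet:
    """Greedy LD clumping with strength filtering.

    Candidates with ``pval < p_threshold`` are sorted by ascending p-value
    (ties broken by snp_id, so row order never matters). The best remaining
    SNP is kept and every other candidate within ``clump_kb`` of it *and*
    with pairwise r^2 > ``clump_r2`` is removed; survivors are then
    filtered to F > ``f_min``.

    Without an LD matrix, SNPs at the same locus are treated as perfectly
    correlated and SNPs at distinct loci as independent.
    """
    candidates = [r for r in table.records if r.pval < config.p_threshold]
    if not candidates:
        raise NoInstrumentsError(
            f"no candidates below p={config.p_threshold:g} for {table.trait_name}"
        )
    if ld is not None:
        _check_ld(ld, [r.snp_id for r in candidates])
    candidates.sort(key=lambda r: (r.pval, r.snp_id))
    kept = []
    remaining = list(candidates)
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        remaining = [
            r
            for r in remaining
            if not (
                _within_window(lead, r, config.clump_kb)
                and _pairwise_r2(lead, r, ld) > config.clump_r2
            )
        ]
    per_r2, per_f = {}, {}
    strong = []
    for rec in kept:
        r2, f = compute_r2_f(rec.beta, rec.eaf, rec.n)
        if f > config.f_min:
            strong.append(rec)
            per_r2[rec.snp_id] = r2
            per_f[rec.snp_id] = f
    if not strong:
        raise NoInstrumentsError(f"no valid instruments for {table.trait_name} (all F <= {config.f_min:g})")
    # emit in selection (p-value) order so output is independent of input row order
    selected = SummaryStatTable(table.trait_name, table.trait_type, list(strong))
    return InstrumentSet(table.trait_name, selected, per_r2, per_f)
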