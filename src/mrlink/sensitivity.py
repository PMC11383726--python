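"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q measures weighted dispersion of the Wald ratios around the
IVW estimate (chi-square with k - 1 df under homogeneity). MR-PRESSO is a
simulation-based residual-sum-of-squares framework with a global
(pleiotropy) test, per-SNP outlier tests and a distortion test comparing
the causal estimate before and after outlier removal. Leave-one-out
re-estimates IVW excluding each SNP in turn. Scatter and funnel plot data
are exported as plain tables; no figures are rendered here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .estimators import EggerFit, MREstimate, _ivw_core, ivw, wald_ratio
from .gwas_io import HarmonizedInstrumentSet

log = logging.getLogger(__name__)

__all__ = [
    "QTest",
    "PressoResult",
    "LooSeries",
    "cochran_q",
    "mr_presso",
    "leave_one_out",
    "plot_data",
    "sensitivity_summary",
]


@dataclass
class QTest:
    q: float
    df: int
    pval: float


def cochran_q(hset: HarmonizedInstrumentSet) -> QTest:
    """Q = sum_j w_j (ratio_j - beta_IVW)^2 with w_j = (beta_Xj / se_Yj)^2."""
    if hset.nsnp < 2:
        raise InputError("Cochran's Q requires at least 2 instruments")
    bx, _, by, sy = hset.arrays()
    _, _, q = _ivw_core(bx, by, sy)
    df = hset.nsnp - 1
    return QTest(q, df, float(stats.chi2.sf(q, df)))


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outliers: list[str]
    distortion_pval: float | None
    estimate_raw: MREstimate
    estimate_corrected: MREstimate | None


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope leaving each SNP out, computed from running sums.

    ``bx``/``by`` may be (k,) or (nsim, k); ``w`` is (k,)."""
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    hset: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    *,
    seed: int,
    sig: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is the weighted residual sum of squares of each
    SNP around the IVW fit that excludes it. The null distribution comes
    from ``n_sim`` parametric simulations drawing both effect columns from
    normals centred on the leave-one-out fitted values; Monte-Carlo
    p-values use the add-one rule so they are never exactly zero. Per-SNP
    outlier p-values are Bonferroni-flagged at ``sig / k``; when outliers
    are flagged a single re-estimation without them is performed and the
    distortion test compares the raw and corrected estimates against
    random-subset removals.
    """
    k = hset.nsnp
    if k < 4:
        raise InputError("MR-PRESSO requires at least 4 instruments")
    if 1.0 / (n_sim + 1.0) >= sig / k:
        log.warning(
            "n_sim=%d cannot reach the Bonferroni outlier threshold %.2g/%d; "
            "no outlier can be flagged", n_sim, sig, k,
        )
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = hset.arrays()
    snps = list(hset.rows["snp"])
    w = 1.0 / sy**2

    b_loo = _loo_slopes(bx, by, w)
    res_obs = w * (by - b_loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    # parametric null: both columns resampled around the LOO expectations
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(b_loo * bx, sy, size=(n_sim, k))
    b_loo_sim = _loo_slopes(bx_sim, by_sim, w)
    res_sim = w * (by_sim - b_loo_sim * bx_sim) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_pval = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_sim + 1.0)
    outlier_pvals = {
        snp: (1.0 + float(np.sum(res_sim[:, j] >= res_obs[j]))) / (n_sim + 1.0)
        for j, snp in enumerate(snps)
    }
    threshold = sig / k
    outliers = [s for s in snps if outlier_pvals[s] < threshold]

    estimate_raw = ivw(hset, effects_model="auto")
    estimate_corrected = None
    distortion_pval = None
    if outliers and k - len(outliers) >= 2:
        keep_mask = ~hset.rows["snp"].isin(outliers).to_numpy()
        corrected_set = HarmonizedInstrumentSet(
            hset.exposure_name, hset.outcome_name, hset.rows.loc[keep_mask].reset_index(drop=True)
        )
        estimate_corrected = ivw(corrected_set, effects_model="auto")
        d_obs = estimate_raw.beta - estimate_corrected.beta
        n_out = len(outliers)
        d_sim = np.empty(n_sim)
        idx = np.arange(k)
        for s in range(n_sim):
            drop = rng.choice(idx, size=n_out, replace=False)
            mask = np.ones(k, bool)
            mask[drop] = False
            b_sub, _, _ = _ivw_core(bx[mask], by[mask], sy[mask])
            d_sim[s] = estimate_raw.beta - b_sub
        distortion_pval = (1.0 + float(np.sum(np.abs(d_sim) >= abs(d_obs)))) / (n_sim + 1.0)
    return PressoResult(
        rss_obs, global_pval, outlier_pvals, outliers, distortion_pval,
        estimate_raw, estimate_corrected,
    )


@dataclass
class LooSeries:
    entries: list[tuple[str, MREstimate]]
    full_estimate: MREstimate

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"left_out": snp, "beta": e.beta, "se": e.se, "pval": e.pval,
             "or": e.or_, "ci_low": e.ci_low, "ci_high": e.ci_high}
            for snp, e in self.entries
        ]
        rows.append({"left_out": "(none)", "beta": self.full_estimate.beta,
                     "se": self.full_estimate.se, "pval": self.full_estimate.pval,
                     "or": self.full_estimate.or_, "ci_low": self.full_estimate.ci_low,
                     "ci_high": self.full_estimate.ci_high})
        return pd.DataFrame(rows)


def leave_one_out(hset: HarmonizedInstrumentSet, effects_model: str = "auto") -> LooSeries:
    """IVW estimate on the instrument set minus each SNP in turn."""
    if hset.nsnp < 2:
        raise InputError("leave-one-out requires at least 2 instruments")
    full = ivw(hset, effects_model=effects_model)
    entries = []
    for j, snp in enumerate(hset.rows["snp"]):
        sub = hset.rows.drop(index=hset.rows.index[j]).reset_index(drop=True)
        subset = HarmonizedInstrumentSet(hset.exposure_name, hset.outcome_name, sub)
        if subset.nsnp == 1:
            r = subset.rows.iloc[0]
            est = wald_ratio(r["beta_exp"], r["se_exp"], r["beta_out"], r["se_out"])
        else:
            est = ivw(subset, effects_model=effects_model)
        entries.append((str(snp), est))
    return LooSeries(entries, full)


def plot_data(hset: HarmonizedInstrumentSet, estimates, egger_fit: EggerFit | None = None) -> dict[str, pd.DataFrame]:
    """Scatter/funnel plot tables for an exposure-outcome pair.

    ``estimates`` is an iterable of :class:`MREstimate`; fitted lines get
    slope = estimate beta and intercept 0, except MR-Egger which uses its
    own intercept when ``egger_fit`` is supplied.
    """
    bx, sx, by, sy = hset.arrays()
    scatter = pd.DataFrame({
        "snp": hset.rows["snp"],
        "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy,
    })
    lines = []
    for est in estimates:
        intercept = 0.0
        if est.method == "egger" and egger_fit is not None:
            intercept = egger_fit.intercept
        lines.append({"method": est.method, "slope": est.beta, "intercept": intercept})
    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    funnel = pd.DataFrame({"snp": hset.rows["snp"], "ratio": ratios, "precision": 1.0 / se_ratio})
    return {"scatter": scatter, "lines": pd.DataFrame(lines), "funnel": funnel}


def sensitivity_summary(
    exposure: str,
    outcome: str,
    q_test: QTest | None,
    egger_fit: EggerFit | None,
    presso: PressoResult | None,
) -> pd.DataFrame:
    """One-row diagnostics table for an exposure-outcome pair."""
    row = {
        "exposure": exposure,
        "outcome": outcome,
        "Q": q_test.q if q_test else np.nan,
        "Q_df": q_test.df if q_test else np.nan,
        "Q_pval": q_test.pval if q_test else np.nan,
        "egger_intercept": egger_fit.intercept if egger_fit else np.nan,
        "intercept_pval": egger_fit.intercept_pval if egger_fit else np.nan,
        "presso_global_pval": presso.global_pval if presso else np.nan,
        "n_outliers": len(presso.outliers) if presso else np.nan,
        "distortion_pval": presso.distortion_pval if presso and presso.distortion_pval is not None else np.nan,
    }
    return pd.DataFrame([row])
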