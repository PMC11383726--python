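"""The five two-sample MR causal estimators and reporting transforms.

All estimators consume a :class:`~mrlink.gwas_io.HarmonizedInstrumentSet`
holding per-SNP exposure effects ``beta_X`` (with SE) and outcome effects
``beta_Y`` (with SE) on a shared effect-allele orientation.

* Wald ratio: per-SNP estimate ``beta_Y / beta_X`` with first-order SE.
* IVW: inverse-variance-weighted combination of Wald ratios, identical to
  weighted least squares of ``beta_Y`` on ``beta_X`` through the origin
  with weights ``1/se_Y^2``. Under the ``auto`` effects model the SE is
  inflated multiplicatively by ``sqrt(max(1, Q/(k-1)))`` when Cochran's Q
  detects heterogeneity.
* MR-Egger: the same weighted regression *with* an intercept, after
  orienting all ``beta_X >= 0``; a nonzero intercept indicates directional
  pleiotropy and the slope remains consistent under InSIDE.
* Weighted median: the weight-0.5 quantile of ordered Wald ratios under
  normalized inverse-variance weights; consistent when at least half of
  the weight comes from valid instruments.
* Mode-based estimators (weighted and simple): the maximizer of a
  Gaussian-kernel-smoothed density of Wald ratios.

Median and mode SEs come from a seeded parametric bootstrap; seeds are a
required argument, there is no hidden global RNG.

Binary-outcome effects are log-odds throughout; :func:`to_odds_ratio`
converts to OR with 1.96-SE normal 95% bounds only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InputError
from .gwas_io import HarmonizedInstrumentSet

__all__ = [
    "MREstimate",
    "EggerFit",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "to_odds_ratio",
    "METHOD_LABELS",
]

METHOD_LABELS = {
    "wald": "Wald ratio",
    "ivw_fixed": "Inverse variance weighted (fixed effects)",
    "ivw_random": "Inverse variance weighted (multiplicative random effects)",
    "egger": "MR Egger",
    "weighted_median": "Weighted median",
    "weighted_mode": "Weighted mode",
    "simple_mode": "Simple mode",
}


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect into OR with normal 95% bounds."""
    if se <= 0:
        raise InputError("se must be positive")
    return float(np.exp(beta)), float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))


@dataclass
class MREstimate:
    """One method's causal estimate for an exposure-outcome pair."""

    method: str
    beta: float
    se: float
    pval: float
    nsnp: int
    or_: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, nsnp: int,
                     t_df: int | None = None) -> "MREstimate":
        """Assemble an estimate; two-sided normal p, or Student t when
        ``t_df`` is given (MR-Egger)."""
        beta, se = float(beta), float(se)
        if se > 0:
            z = abs(beta) / se
            pval = 2.0 * (stats.t.sf(z, t_df) if t_df else stats.norm.sf(z))
            or_, lo, hi = to_odds_ratio(beta, se)
        else:  # degenerate zero-variance case (e.g. identical ratios)
            pval = 1.0 if beta == 0 else float(np.finfo(float).tiny)
            or_ = lo = hi = float(np.exp(beta))
        return cls(method, beta, se, float(min(pval, 1.0)), int(nsnp), or_, lo, hi)


@dataclass
class EggerFit:
    """MR-Egger slope plus the intercept (directional-pleiotropy) test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-SNP causal estimate ``beta_out / beta_exp``, first-order SE."""
    if beta_exp == 0:
        raise InputError("wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate.from_beta_se("wald", beta, se, 1)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """(beta, fixed-effect se, Cochran Q) for the IVW fit through the origin."""
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx**-0.5
    ratios = by / bx
    wq = (bx / sy) ** 2
    q = float(np.sum(wq * (ratios - beta) ** 2))
    return beta, se_fixed, q


def ivw(
    hset: HarmonizedInstrumentSet,
    effects_model: str = "auto",
    q_alpha: float = 0.05,
) -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``effects_model``: ``fixed`` | ``random`` | ``auto``. Under ``auto``
    the fixed-effect model is kept unless Cochran's Q has p < ``q_alpha``
    (requires k >= 2), in which case the SE is inflated by
    ``sqrt(max(1, Q/(k-1)))`` and the method tagged ``ivw_random``.
    """
    if hset.nsnp == 0:
        raise InputError("empty instrument set")
    if effects_model not in ("auto", "fixed", "random"):
        raise InputError(f"unknown effects_model {effects_model!r}")
    bx, _, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise InputError("beta_exp = 0 in instrument set")
    beta, se, q = _ivw_core(bx, by, sy)
    k = hset.nsnp
    method = "ivw_fixed"
    if k >= 2:
        inflation = np.sqrt(max(1.0, q / (k - 1)))
        q_pval = stats.chi2.sf(q, k - 1)
        if effects_model == "random" or (effects_model == "auto" and q_pval < q_alpha):
            se *= inflation
            method = "ivw_random"
    return MREstimate.from_beta_se(method, beta, se, k)


def egger(hset: HarmonizedInstrumentSet) -> EggerFit:
    """Weighted regression of beta_Y on beta_X with intercept (MR-Egger).

    Exposure effects are oriented nonnegative first (flipping beta_Y
    jointly). SEs use a multiplicative random-effects scale floored at the
    fixed-effect value; tests use Student t with k - 2 df.
    """
    k = hset.nsnp
    if k < 3:
        raise InputError("MR-Egger requires at least 3 instruments")
    bx, _, by, sy = hset.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (k - 2)
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    slope_est = MREstimate.from_beta_se("egger", slope, se_slope, k, t_df=k - 2)
    int_p = float(min(1.0, 2.0 * stats.t.sf(abs(intercept) / se_int, k - 2))) if se_int > 0 else 1.0
    return EggerFit(slope_est, intercept, se_int, int_p)


def _wald_ratios_weights(hset: HarmonizedInstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    bx, _, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise InputError("beta_exp = 0 in instrument set")
    ratios = by / bx
    weights = (bx / sy) ** 2
    return ratios, weights / weights.sum()


def _weighted_quantile_half(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-0.5 quantile of the ratios with linear interpolation."""
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def _bootstrap_se(hset: HarmonizedInstrumentSet, estimator, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: resample (beta_X, beta_Y) from their normals."""
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = hset.arrays()
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = np.finfo(float).tiny
        est[b] = estimator(bys / bxs, (bxs / sy) ** 2)
    return float(np.std(est, ddof=1))


def weighted_median(hset: HarmonizedInstrumentSet, n_boot: int = 1000, *, seed: int) -> MREstimate:
    """Weighted-median estimator with seeded parametric-bootstrap SE."""
    if hset.nsnp < 3:
        raise InputError("weighted median requires at least 3 instruments")
    ratios, weights = _wald_ratios_weights(hset)
    beta = _weighted_quantile_half(ratios, weights)
    se = _bootstrap_se(
        hset, lambda r, w: _weighted_quantile_half(r, w / w.sum()), n_boot, seed
    )
    return MREstimate.from_beta_se("weighted_median", beta, se, hset.nsnp)


def _mad(x: np.ndarray) -> float:
    # scaled median absolute deviation (consistent for the normal sd)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _smoothed_mode(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    k = len(ratios)
    spread = min(np.std(ratios, ddof=1), _mad(ratios)) if k > 1 else 0.0
    h = phi * 0.9 * spread / k**0.2
    if h <= 0 or not np.isfinite(h):
        # degenerate: (near-)identical ratios; heaviest point wins
        return float(ratios[np.argmax(weights)])
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 1024)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[np.argmax(dens)])


def mode_estimate(
    hset: HarmonizedInstrumentSet,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    *,
    seed: int,
) -> MREstimate:
    """Mode-based estimate: the maximizer of the kernel-smoothed Wald-ratio
    density.

    ``weighted=True`` uses normalized inverse-variance weights (weighted
    mode); ``weighted=False`` uses uniform weights (simple mode). The
    bandwidth is ``phi`` times a modified Silverman rule,
    ``0.9 * min(sd, MAD) / k^(1/5)``. SE from a seeded parametric
    bootstrap.
    """
    if hset.nsnp < 3:
        raise InputError("mode estimators require at least 3 instruments")
    ratios, ivw_weights = _wald_ratios_weights(hset)
    k = hset.nsnp

    def pick_weights(w_iv):
        return w_iv / w_iv.sum() if weighted else np.full(len(w_iv), 1.0 / len(w_iv))

    beta = _smoothed_mode(ratios, pick_weights(ivw_weights), phi)
    se = _bootstrap_se(hset, lambda r, w: _smoothed_mode(r, pick_weights(w), phi), n_boot, seed)
    return MREstimate.from_beta_se("weighted_mode" if weighted else "simple_mode", beta, se, k)
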