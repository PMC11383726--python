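"""Two-step mediation MR: indirect effects, screening and reporting.

The two-step design estimates (1) exposure -> mediator (``beta1``),
(2) mediator -> outcome (``beta2``) and (3) the total exposure -> outcome
effect (``beta_all``), each by IVW on its own instruments. The indirect
(mediated) effect is the product ``beta1 * beta2`` with a delta-method
(Sobel) standard error

    se = sqrt(beta1^2 * se2^2 + beta2^2 * se1^2),

normal 95% CI and two-sided p. A seeded Monte-Carlo product-of-normals
interval is available as an alternative. The direct effect is
``beta_all - indirect`` and the proportion mediated is
``indirect / beta_all`` (on the log-odds scale when the outcome is
binary; undefined when ``beta_all`` is zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .estimators import MREstimate

__all__ = [
    "IndirectEffect",
    "MediationResult",
    "indirect_effect",
    "screen_mediators",
    "mediation_report",
]


@dataclass
class IndirectEffect:
    indirect: float
    se: float
    ci_low: float
    ci_high: float
    pval: float


def indirect_effect(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    method: str = "delta",
    n_draws: int = 100_000,
    seed: int | None = None,
) -> IndirectEffect:
    """Product-of-coefficients indirect effect with uncertainty.

    ``method="delta"`` (default) uses the Sobel SE and normal bounds;
    ``method="mc"`` draws the two coefficients from their normals and
    takes percentile bounds (requires ``seed``).
    """
    if se1 <= 0 or se2 <= 0:
        raise InputError("standard errors must be positive")
    point = beta1 * beta2
    se = float(np.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2))
    if method == "delta":
        lo, hi = point - 1.96 * se, point + 1.96 * se
    elif method == "mc":
        if seed is None:
            raise InputError("Monte-Carlo intervals require a seed")
        rng = np.random.default_rng(seed)
        draws = rng.normal(beta1, se1, n_draws) * rng.normal(beta2, se2, n_draws)
        lo, hi = np.percentile(draws, [2.5, 97.5])
    else:
        raise InputError(f"unknown method {method!r}")
    pval = 1.0 if se == 0 else float(min(1.0, 2.0 * stats.norm.sf(abs(point) / se)))
    return IndirectEffect(float(point), se, float(lo), float(hi), pval)


@dataclass
class MediationResult:
    """Decomposition of one exposure -> mediator -> outcome pathway."""

    exposure: str
    mediator: str
    outcome: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta_all: float
    se_all: float
    indirect: float
    indirect_se: float
    ci_low: float
    ci_high: float
    pval: float
    direct: float
    proportion: float  # NaN when beta_all == 0
    significant: bool

    @classmethod
    def build(
        cls,
        exposure: str,
        mediator: str,
        outcome: str,
        step1: MREstimate,
        step2: MREstimate,
        total: MREstimate,
        alpha: float = 0.05,
        ci_method: str = "delta",
        seed: int | None = None,
    ) -> "MediationResult":
        eff = indirect_effect(step1.beta, step1.se, step2.beta, step2.se,
                              method=ci_method, seed=seed)
        proportion = eff.indirect / total.beta if total.beta != 0 else float("nan")
        return cls(
            exposure, mediator, outcome,
            step1.beta, step1.se, step2.beta, step2.se,
            total.beta, total.se,
            eff.indirect, eff.se, eff.ci_low, eff.ci_high, eff.pval,
            total.beta - eff.indirect, proportion, bool(eff.pval < alpha),
        )


def screen_mediators(
    step1: Mapping[str, MREstimate],
    step2: Mapping[str, MREstimate],
    total: MREstimate,
    exposure: str = "exposure",
    outcome: str = "outcome",
    alpha: float = 0.05,
    ci_method: str = "delta",
    seed: int | None = None,
) -> list[MediationResult]:
    """Select candidate mediators and assemble their decompositions.

    A mediator is a candidate when both its exposure->mediator and
    mediator->outcome estimates have p < ``alpha``. Candidates are paired
    with the total exposure->outcome estimate into
    :class:`MediationResult` objects, in sorted mediator order.
    """
    candidates = []
    for name in sorted(step1):
        if name not in step2:
            continue
        if step1[name].pval < alpha and step2[name].pval < alpha:
            candidates.append(
                MediationResult.build(
                    exposure, name, outcome, step1[name], step2[name], total,
                    alpha=alpha, ci_method=ci_method, seed=seed,
                )
            )
    return candidates


def mediation_report(results: list[MediationResult]) -> pd.DataFrame:
    """Tabulate mediation decompositions (tab-serializable).

    The ``proportion`` column is NaN (undefined) when the total effect is
    zero; ``significant`` honours p < .05 on the indirect effect.
    """
    return pd.DataFrame(
        [
            {
                "exposure": r.exposure,
                "mediator": r.mediator,
                "outcome": r.outcome,
                "beta1": r.beta1,
                "se1": r.se1,
                "beta2": r.beta2,
                "se2": r.se2,
                "beta_all": r.beta_all,
                "se_all": r.se_all,
                "indirect": r.indirect,
                "indirect_se": r.indirect_se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "pval": r.pval,
                "direct": r.direct,
                "proportion": r.proportion,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "exposure", "mediator", "outcome", "beta1", "se1", "beta2", "se2",
            "beta_all", "se_all", "indirect", "indirect_se", "ci_low", "ci_high",
            "pval", "direct", "proportion", "significant",
        ],
    )
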