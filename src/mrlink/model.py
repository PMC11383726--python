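"""Model/Results facade for a single exposure-outcome MR analysis.

:class:`MRModel` wraps instrument selection, harmonization and the full
estimator battery behind the familiar model/fit/results pattern::

    model = MRModel.from_tables(exposure, outcome, ld=ld)
    res = model.fit(seed=7)
    print(res.summary())
    presso = res.run_presso(n_sim=1000, seed=11)

``fit`` always computes the IVW estimate (with the Cochran-Q random
effects fallback) and, when at least three instruments are available,
MR-Egger, the weighted median and both mode estimators, plus the Egger
intercept pleiotropy test. MR-PRESSO and leave-one-out hang off the
results object because they carry their own simulation settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import InputError
from .estimators import (
    METHOD_LABELS,
    EggerFit,
    MREstimate,
    egger,
    ivw,
    mode_estimate,
    wald_ratio,
    weighted_median,
)
from .gwas_io import HarmonizedInstrumentSet, SummaryStatTable, harmonize
from .instruments import ClumpConfig, InstrumentSet, clump
from .sensitivity import (
    LooSeries,
    PressoResult,
    QTest,
    cochran_q,
    leave_one_out,
    mr_presso,
    plot_data,
    sensitivity_summary,
)

__all__ = ["MRModel", "MRResults"]


class MRModel:
    """Two-sample summary-data MR model for one exposure-outcome pair."""

    def __init__(self, hset: HarmonizedInstrumentSet,
                 instruments: InstrumentSet | None = None):
        if hset.nsnp == 0:
            raise InputError("harmonized set is empty")
        self.hset = hset
        self.instruments = instruments

    @classmethod
    def from_tables(
        cls,
        exposure: SummaryStatTable,
        outcome: SummaryStatTable,
        clump_config: ClumpConfig = ClumpConfig(),
        ld: pd.DataFrame | None = None,
        palindrome_eaf_window: float = 0.08,
    ) -> "MRModel":
        """Select instruments from ``exposure``, harmonize against
        ``outcome`` and build the model."""
        selected = clump(exposure, clump_config, ld)
        hset = harmonize(selected.table, outcome, palindrome_eaf_window)
        return cls(hset, instruments=selected)

    @property
    def nsnp(self) -> int:
        return self.hset.nsnp

    def fit(
        self,
        *,
        seed: int,
        effects_model: str = "auto",
        q_alpha: float = 0.05,
        n_boot: int = 1000,
        phi: float = 1.0,
        methods: tuple[str, ...] | None = None,
    ) -> "MRResults":
        """Run the estimator battery; ``methods`` restricts which of
        egger/weighted_median/weighted_mode/simple_mode run (IVW always
        does)."""
        k = self.nsnp
        wanted = set(methods) if methods is not None else {
            "egger", "weighted_median", "weighted_mode", "simple_mode",
        }
        estimates: dict[str, MREstimate] = {}
        if k == 1:
            r = self.hset.rows.iloc[0]
            estimates["wald"] = wald_ratio(r["beta_exp"], r["se_exp"], r["beta_out"], r["se_out"])
        est_ivw = ivw(self.hset, effects_model=effects_model, q_alpha=q_alpha)
        estimates[est_ivw.method] = est_ivw
        q_test = cochran_q(self.hset) if k >= 2 else None
        egger_fit: EggerFit | None = None
        if k >= 3:
            if "egger" in wanted:
                egger_fit = egger(self.hset)
                estimates["egger"] = egger_fit.slope
            if "weighted_median" in wanted:
                estimates["weighted_median"] = weighted_median(self.hset, n_boot=n_boot, seed=seed)
            if "weighted_mode" in wanted:
                estimates["weighted_mode"] = mode_estimate(
                    self.hset, weighted=True, phi=phi, n_boot=n_boot, seed=seed + 1)
            if "simple_mode" in wanted:
                estimates["simple_mode"] = mode_estimate(
                    self.hset, weighted=False, phi=phi, n_boot=n_boot, seed=seed + 2)
        return MRResults(self, estimates, q_test, egger_fit)


@dataclass
class MRResults:
    """Fitted estimates and diagnostics for one exposure-outcome pair."""

    model: MRModel
    estimates: dict[str, MREstimate]
    q_test: QTest | None
    egger_fit: EggerFit | None
    presso: PressoResult | None = field(default=None)

    @property
    def ivw(self) -> MREstimate:
        for key in ("ivw_random", "ivw_fixed", "wald"):
            if key in self.estimates:
                return self.estimates[key]
        raise KeyError("no IVW estimate present")

    def estimates_frame(self) -> pd.DataFrame:
        """One row per method: nsnp, beta, se, pval, OR and CI bounds."""
        hset = self.model.hset
        rows = [
            {
                "exposure": hset.exposure_name,
                "outcome": hset.outcome_name,
                "method": est.method,
                "nsnp": est.nsnp,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "or": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
            for est in self.estimates.values()
        ]
        return pd.DataFrame(rows)

    def run_presso(self, n_sim: int = 1000, *, seed: int, sig: float = 0.05) -> PressoResult:
        self.presso = mr_presso(self.model.hset, n_sim=n_sim, seed=seed, sig=sig)
        return self.presso

    def leave_one_out(self) -> LooSeries:
        return leave_one_out(self.model.hset)

    def plot_data(self) -> dict[str, pd.DataFrame]:
        return plot_data(self.model.hset, self.estimates.values(), self.egger_fit)

    def sensitivity_report(self) -> pd.DataFrame:
        hset = self.model.hset
        return sensitivity_summary(
            hset.exposure_name, hset.outcome_name, self.q_test, self.egger_fit, self.presso
        )

    def summary(self) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        hset = self.model.hset
        lines = [
            "Two-sample Mendelian randomization",
            "=" * 70,
            f"Exposure: {hset.exposure_name}",
            f"Outcome:  {hset.outcome_name}",
            f"Instruments (after harmonization): {hset.nsnp}",
            "-" * 70,
            f"{'method':<42}{'beta':>8}{'se':>7}{'p':>8}",
        ]
        for est in self.estimates.values():
            label = METHOD_LABELS.get(est.method, est.method)
            lines.append(f"{label:<42}{est.beta:>8.3f}{est.se:>7.3f}{est.pval:>8.3g}")
            lines.append(f"{'':<42}OR {est.or_:.3f} (95% CI {est.ci_low:.3f}-{est.ci_high:.3f})")
        lines.append("-" * 70)
        if self.q_test is not None:
            lines.append(
                f"Cochran's Q = {self.q_test.q:.3f} (df {self.q_test.df}, p = {self.q_test.pval:.3g})"
            )
        if self.egger_fit is not None:
            lines.append(
                f"Egger intercept = {self.egger_fit.intercept:.4f} "
                f"(se {self.egger_fit.intercept_se:.4f}, p = {self.egger_fit.intercept_pval:.3g})"
            )
        if self.presso is not None:
            lines.append(
                f"MR-PRESSO global p = {self.presso.global_pval:.3g}, "
                f"outliers: {len(self.presso.outliers)}"
            )
        return "\n".join(lines)
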