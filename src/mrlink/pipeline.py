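"""Orchestration of multi-trait MR screens, bidirectional runs and
mediation assembly.

The screen mirrors the common panel design: many exposures against one
outcome, with the IVW p-value as the sole decision criterion (secondary
estimators are reported but never gate the "positive" flag). Pairs that
yield no analyzable instruments are recorded as skips, not failures, so
a degenerate panel member cannot abort a screen. No multiple-testing
correction is applied to the flags; a Benjamini-Hochberg FDR column is
emitted for the reader's judgement only.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from scipy import stats

from .exceptions import InputError, NoInstrumentsError
from .estimators import MREstimate
from .gwas_io import SummaryStatTable
from .instruments import ClumpConfig
from .mediation import mediation_report, screen_mediators
from .model import MRModel, MRResults

log = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_pair", "run_screen", "run_bidirectional", "run_mediation"]


@dataclass
class AnalysisConfig:
    """Settings for a full analysis run; seeds are always explicit."""

    clump: ClumpConfig = field(default_factory=ClumpConfig)
    q_alpha: float = 0.05
    n_boot: int = 1000
    phi: float = 1.0
    presso_nsim: int = 1000
    presso_sig: float = 0.05
    seed: int = 0
    alpha: float = 0.05
    palindrome_eaf_window: float = 0.08
    run_presso: bool = True
    methods: tuple[str, ...] | None = None  # None = all secondary estimators

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise InputError("alpha must be in (0,1)")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        clump_keys = {f.name for f in dataclasses.fields(ClumpConfig)}
        clump_kwargs = {k: d.pop(k) for k in list(d) if k in clump_keys}
        if "methods" in d and d["methods"] is not None:
            d["methods"] = tuple(d["methods"])
        cfg = cls(clump=ClumpConfig(**clump_kwargs), **d)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        """Load from a flat YAML key-value file (clumping keys and
        analysis keys side by side)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"config file {path} must hold a flat mapping")
        return cls.from_dict(data)


def run_pair(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    config: AnalysisConfig = AnalysisConfig(),
    ld: pd.DataFrame | None = None,
) -> MRResults | None:
    """Full single-pair analysis: instruments, harmonization, all
    estimators and diagnostics; PRESSO-corrected IVW appended when
    outliers are flagged. Returns None (a skip) when no instruments
    survive."""
    try:
        model = MRModel.from_tables(
            exposure, outcome, config.clump, ld, config.palindrome_eaf_window
        )
    except NoInstrumentsError as exc:
        log.info("skipped pair %s ~ %s: %s", exposure.trait_name, outcome.trait_name, exc)
        return None
    res = model.fit(
        seed=config.seed, q_alpha=config.q_alpha, n_boot=config.n_boot,
        phi=config.phi, methods=config.methods,
    )
    if config.run_presso and model.nsnp >= 4:
        presso = res.run_presso(n_sim=config.presso_nsim, seed=config.seed + 10_000,
                                sig=config.presso_sig)
        if presso.estimate_corrected is not None:
            corrected = presso.estimate_corrected
            res.estimates["ivw_outlier_corrected"] = MREstimate(
                "ivw_outlier_corrected", corrected.beta, corrected.se,
                corrected.pval, corrected.nsnp, corrected.or_,
                corrected.ci_low, corrected.ci_high,
            )
    return res


def run_screen(
    exposures: dict[str, SummaryStatTable],
    outcome: SummaryStatTable,
    config: AnalysisConfig = AnalysisConfig(),
    ld: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, MRResults]]:
    """Screen many exposures against one outcome.

    Returns (estimates table, sensitivity table, results by exposure).
    The ``positive`` flag comes from the IVW p-value alone; an ``fdr``
    column (Benjamini-Hochberg over the IVW p-values) is informational.
    """
    frames, sens_frames, results = [], [], {}
    for name in sorted(exposures):
        res = run_pair(exposures[name], outcome, config, ld)
        if res is None:
            continue
        results[name] = res
        frame = res.estimates_frame()
        ivw_p = res.ivw.pval
        frame["ivw_pval"] = ivw_p
        frame["positive"] = ivw_p < config.alpha
        frames.append(frame)
        sens_frames.append(res.sensitivity_report())
    if not frames:
        empty = pd.DataFrame(columns=[
            "exposure", "outcome", "method", "nsnp", "beta", "se", "pval",
            "or", "ci_low", "ci_high", "ivw_pval", "positive", "fdr",
        ])
        return empty, pd.DataFrame(), {}
    table = pd.concat(frames, ignore_index=True)
    ivw_p_by_exposure = {name: res.ivw.pval for name, res in results.items()}
    names = sorted(ivw_p_by_exposure)
    fdr = stats.false_discovery_control([ivw_p_by_exposure[n] for n in names])
    fdr_map = dict(zip(names, fdr))
    table["fdr"] = table["exposure"].map(fdr_map)
    sens = pd.concat(sens_frames, ignore_index=True)
    return table, sens, results


def run_bidirectional(
    exposures: dict[str, SummaryStatTable],
    outcome: SummaryStatTable,
    config: AnalysisConfig = AnalysisConfig(),
    ld: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward screen (exposures -> outcome) and reverse MR (outcome as
    exposure against each panel trait).

    In the reverse direction a binary trait's log-odds betas are used as
    exposure effects unchanged; this standard practice is logged as a
    caveat since the causal estimate is then per log-odds unit.
    """
    forward, _, _ = run_screen(exposures, outcome, config, ld)
    if outcome.trait_type == "binary":
        log.warning(
            "reverse direction uses binary trait %s as exposure: betas on log-odds scale",
            outcome.trait_name,
        )
    reverse_frames = []
    for name in sorted(exposures):
        res = run_pair(outcome, exposures[name], config, ld)
        if res is None:
            continue
        frame = res.estimates_frame()
        frame["positive"] = res.ivw.pval < config.alpha
        if res.model.instruments is not None:
            f_vals = list(res.model.instruments.per_snp_f.values())
            frame["min_F"] = min(f_vals)
            frame["max_F"] = max(f_vals)
        reverse_frames.append(frame)
    reverse = (
        pd.concat(reverse_frames, ignore_index=True)
        if reverse_frames
        else pd.DataFrame()
    )
    return forward, reverse


def run_mediation(
    exposure: SummaryStatTable,
    mediators: dict[str, SummaryStatTable],
    outcome: SummaryStatTable,
    config: AnalysisConfig = AnalysisConfig(),
    ld: pd.DataFrame | None = None,
    ci_method: str = "delta",
) -> pd.DataFrame:
    """Two-step mediation: exposure -> mediator (beta1), mediator ->
    outcome (beta2), exposure -> outcome total (beta_all); mediators with
    both step p-values below ``alpha`` are decomposed."""
    total_res = run_pair(exposure, outcome, config, ld)
    if total_res is None:
        raise NoInstrumentsError(
            f"no instruments for total effect {exposure.trait_name} -> {outcome.trait_name}"
        )
    step1: dict[str, MREstimate] = {}
    step2: dict[str, MREstimate] = {}
    for name in sorted(mediators):
        r1 = run_pair(exposure, mediators[name], config, ld)
        r2 = run_pair(mediators[name], outcome, config, ld)
        if r1 is not None:
            step1[name] = r1.ivw
        if r2 is not None:
            step2[name] = r2.ivw
    candidates = screen_mediators(
        step1, step2, total_res.ivw,
        exposure=exposure.trait_name, outcome=outcome.trait_name,
        alpha=config.alpha, ci_method=ci_method, seed=config.seed + 20_000,
    )
    return mediation_report(candidates)


def write_results(outdir, results_table: pd.DataFrame | None = None,
                  sensitivity_table: pd.DataFrame | None = None,
                  mediation_table: pd.DataFrame | None = None,
                  plotdata: dict[str, pd.DataFrame] | None = None) -> None:
    """Write analysis outputs as tab-delimited files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if results_table is not None:
        results_table.to_csv(outdir / "results.tsv", sep="\t", index=False)
    if sensitivity_table is not None:
        sensitivity_table.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False)
    if mediation_table is not None:
        mediation_table.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
    if plotdata:
        plotdir = outdir / "plotdata"
        plotdir.mkdir(exist_ok=True)
        for name, frame in plotdata.items():
            frame.to_csv(plotdir / f"{name}.tsv", sep="\t", index=False)
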