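"""Reading, validation and harmonization of GWAS summary statistics.

A summary-statistics table holds one row per SNP: identifier, effect and
other allele, effect-allele frequency (EAF), per-allele effect ``beta``
(log-odds for binary traits), its standard error, p-value and sample size.
Harmonization joins exposure instruments to outcome effects on a shared
effect-allele orientation, resolving swapped and complementary-strand
allele codings and handling palindromic (A/T, G/C) variants by allele
frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError, NoInstrumentsError

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order used by every writer in the package
CANONICAL_COLUMNS = [
    "snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n", "locus",
]

#: header mapping for FinnGen release files
FINNGEN_COLUMN_MAP = {
    "snp": "rsids",
    "effect_allele": "alt",
    "other_allele": "ref",
    "eaf": "af_alt",
    "beta": "beta",
    "se": "sebeta",
    "pval": "pval",
    "n": "n",
    "locus": "pos",
}

#: header mapping for GWAS-Catalog harmonised files
GWAS_CATALOG_COLUMN_MAP = {
    "snp": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pval": "p_value",
    "n": "n",
    "locus": "base_pair_location",
}


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and G/C allele pairs, whose strand is ambiguous."""
    return COMPLEMENT.get(a1) == a2


@dataclass
class SummaryStatRecord:
    """One SNP-trait association from a GWAS summary file."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float
    locus: object | None = None

    def validation_failures(self) -> list[str]:
        """Hard invariant violations; a non-empty list means "drop this row"."""
        reasons = []
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            reasons.append("invalid allele")
        elif self.effect_allele == self.other_allele:
            reasons.append("identical alleles")
        if not (self.se > 0) or not math.isfinite(self.se):
            reasons.append("nonpositive se")
        if not (0.0 < self.eaf < 1.0):
            reasons.append("eaf out of range")
        if not (0.0 < self.pval <= 1.0):
            reasons.append("pval out of range")
        if not (self.n >= 2):
            reasons.append("sample size < 2")
        if not math.isfinite(self.beta):
            reasons.append("non-finite beta")
        return reasons

    def pval_consistent(self, factor: float = 2.0) -> bool:
        """Check the reported p against the two-sided normal p for beta/se.

        Published tables round, so this is a warning-level check: the two
        p-values must agree within a multiplicative ``factor``, compared on
        the log scale so that very small p-values are handled stably.
        """
        if self.se <= 0:
            return False
        z = abs(self.beta) / self.se
        logp_expected = math.log(2.0) + stats.norm.logsf(z)
        logp_reported = math.log(self.pval)
        # a reported p at the float floor is consistent with any smaller p
        tiny = math.log(np.finfo(float).tiny)
        if logp_expected <= tiny and logp_reported <= tiny + math.log(factor):
            return True
        return abs(logp_reported - logp_expected) <= math.log(factor) + 1e-12

    def numeric_locus(self) -> float | None:
        try:
            return float(self.locus)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return None


@dataclass
class SummaryStatTable:
    """All summary-statistics rows for one trait, unique by SNP identifier."""

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    records: list[SummaryStatRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise InputError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise InputError(f"duplicate snp_id in table {self.trait_name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, snp_id: str) -> SummaryStatRecord | None:
        return self._index().get(snp_id)

    def _index(self) -> dict[str, SummaryStatRecord]:
        return {r.snp_id: r for r in self.records}

    def subset(self, snp_ids) -> "SummaryStatTable":
        wanted = set(snp_ids)
        return SummaryStatTable(
            self.trait_name, self.trait_type,
            [r for r in self.records if r.snp_id in wanted],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "snp": r.snp_id,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "eaf": r.eaf,
                    "beta": r.beta,
                    "se": r.se,
                    "pval": r.pval,
                    "n": r.n,
                    "locus": r.locus,
                }
                for r in self.records
            ],
            columns=CANONICAL_COLUMNS,
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        trait_name: str,
        trait_type: str = "continuous",
        validate: bool = True,
    ) -> "SummaryStatTable":
        """Build a validated table from a canonically named DataFrame.

        Rows failing a hard invariant are dropped with a logged reason;
        rows whose p-value disagrees with the normal approximation for
        beta/se only trigger a warning (printed tables round).
        """
        records: list[SummaryStatRecord] = []
        for row in frame.itertuples(index=False):
            d = row._asdict()
            try:
                rec = SummaryStatRecord(
                    snp_id=str(d["snp"]),
                    effect_allele=str(d["effect_allele"]).upper(),
                    other_allele=str(d["other_allele"]).upper(),
                    eaf=float(d["eaf"]),
                    beta=float(d["beta"]),
                    se=float(d["se"]),
                    pval=float(d["pval"]),
                    n=float(d["n"]),
                    locus=d.get("locus"),
                )
            except (TypeError, ValueError) as exc:
                log.info("dropped row %r from %s: unparseable (%s)", d.get("snp"), trait_name, exc)
                continue
            if validate:
                reasons = rec.validation_failures()
                if reasons:
                    log.info("dropped %s from %s: %s", rec.snp_id, trait_name, "; ".join(reasons))
                    continue
                if not rec.pval_consistent():
                    log.warning(
                        "%s in %s: reported p %.3g inconsistent with |beta/se| normal p",
                        rec.snp_id, trait_name, rec.pval,
                    )
            records.append(rec)
        return cls(trait_name, trait_type, records)


def _detect_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise InputError(f"empty file: {path}")
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_summary_stats(
    path,
    column_map: dict | None = None,
    trait_type: str = "continuous",
    trait_name: str | None = None,
    delimiter: str | None = None,
) -> SummaryStatTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path : str or Path
        Tab- or comma-delimited text file with a header row.
    column_map : dict, optional
        Mapping from canonical names (``snp``, ``effect_allele``, ...) to
        the file's column names; ``FINNGEN_COLUMN_MAP`` and
        ``GWAS_CATALOG_COLUMN_MAP`` are provided. Defaults to canonical
        names. ``n`` and ``locus`` are optional in the file; missing ``n``
        raises, missing ``locus`` is tolerated.
    trait_type : {"continuous", "binary"}
        Binary traits are interpreted on the log-odds scale.
    """
    delimiter = delimiter or _detect_delimiter(path)
    raw = pd.read_csv(path, sep=delimiter)
    if raw.empty:
        raise InputError(f"no data rows in {path}")
    column_map = dict(column_map or {})
    frame = pd.DataFrame()
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in raw.columns:
            frame[canonical] = raw[source]
        elif canonical == "locus":
            frame[canonical] = None
        else:
            raise InputError(f"missing required column {source!r} (for {canonical!r}) in {path}")
    name = trait_name or str(path)
    return SummaryStatTable.from_frame(frame, name, trait_type)


def write_summary_stats(table: SummaryStatTable, path) -> None:
    """Write a table tab-delimited with canonical column names.

    Floats are written with ``repr`` precision so a write/read round trip
    reproduces every field exactly.
    """
    table.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedInstrumentSet:
    """Exposure instruments joined to outcome effects, shared orientation.

    ``rows`` has columns snp, beta_exp, se_exp, beta_out, se_out, eaf_exp;
    ``dropped`` records (snp_id, reason) for instruments that could not be
    reconciled.
    """

    exposure_name: str
    outcome_name: str
    rows: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nsnp(self) -> int:
        return len(self.rows)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        r = self.rows
        return (
            r["beta_exp"].to_numpy(float),
            r["se_exp"].to_numpy(float),
            r["beta_out"].to_numpy(float),
            r["se_out"].to_numpy(float),
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        out.insert(0, "exposure", self.exposure_name)
        out.insert(1, "outcome", self.outcome_name)
        return out

    def write(self, path) -> None:
        frame = self.to_frame()
        frame["dropped_reason"] = ""
        dropped = pd.DataFrame(
            [
                {
                    "exposure": self.exposure_name,
                    "outcome": self.outcome_name,
                    "snp": snp,
                    "dropped_reason": reason,
                }
                for snp, reason in self.dropped
            ]
        )
        pd.concat([frame, dropped], ignore_index=True).to_csv(
            path, sep="\t", index=False
        )


def harmonize(
    exposure_instruments: SummaryStatTable,
    outcome: SummaryStatTable,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect-allele orientation.

    For each exposure instrument present in the outcome table:

    * identical allele pair — kept as-is;
    * swapped alleles — ``beta_out`` negated, outcome EAF replaced by
      ``1 - eaf``;
    * complementary-strand pair — strand-flipped then matched as above;
    * palindromic pair (A/T or G/C) — orientation inferred from allele
      frequency, but only when both EAFs lie outside
      ``[0.5 - window, 0.5 + window]``; otherwise dropped as
      ``palindromic-ambiguous``;
    * any other allele combination — dropped as ``allele-mismatch``;
    * instruments absent from the outcome — dropped as ``not-found``.

    Raises :class:`NoInstrumentsError` when nothing survives.
    """
    if len(exposure_instruments) == 0 or len(outcome) == 0:
        raise NoInstrumentsError("harmonize requires nonempty exposure and outcome tables")
    w = float(palindrome_eaf_window)
    out_index = outcome._index()
    kept_rows = []
    dropped: list[tuple[str, str]] = []
    for exp in exposure_instruments:
        out = out_index.get(exp.snp_id)
        if out is None:
            dropped.append((exp.snp_id, "not-found"))
            continue
        e1, e2 = exp.effect_allele, exp.other_allele
        o1, o2 = out.effect_allele, out.other_allele
        beta_out, eaf_out = out.beta, out.eaf
        if is_palindromic(e1, e2):
            if {o1, o2} != {e1, e2}:
                dropped.append((exp.snp_id, "allele-mismatch"))
                continue
            informative = abs(exp.eaf - 0.5) > w and abs(eaf_out - 0.5) > w
            if not informative:
                dropped.append((exp.snp_id, "palindromic-ambiguous"))
                continue
            same_side = (exp.eaf - 0.5) * ((eaf_out if o1 == e1 else 1 - eaf_out) - 0.5) > 0
            if o1 != e1:  # alleles recorded in swapped order; align first
                beta_out, eaf_out = -beta_out, 1 - eaf_out
            if not same_side:  # frequencies disagree: the strands differ
                beta_out, eaf_out = -beta_out, 1 - eaf_out
        else:
            if (o1, o2) == (e1, e2):
                pass
            elif (o1, o2) == (e2, e1):
                beta_out, eaf_out = -beta_out, 1 - eaf_out
            elif (COMPLEMENT[o1], COMPLEMENT[o2]) == (e1, e2):
                pass
            elif (COMPLEMENT[o1], COMPLEMENT[o2]) == (e2, e1):
                beta_out, eaf_out = -beta_out, 1 - eaf_out
            else:
                dropped.append((exp.snp_id, "allele-mismatch"))
                continue
        kept_rows.append(
            {
                "snp": exp.snp_id,
                "beta_exp": exp.beta,
                "se_exp": exp.se,
                "beta_out": beta_out,
                "se_out": out.se,
                "eaf_exp": exp.eaf,
            }
        )
    for snp, reason in dropped:
        log.info("harmonize %s~%s: dropped %s (%s)",
                 exposure_instruments.trait_name, outcome.trait_name, snp, reason)
    if not kept_rows:
        raise NoInstrumentsError(
            f"no analyzable instruments for {exposure_instruments.trait_name} "
            f"on {outcome.trait_name}"
        )
    rows = pd.DataFrame(kept_rows, columns=["snp", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp"])
    return HarmonizedInstrumentSet(
        exposure_instruments.trait_name, outcome.trait_name, rows, dropped
    )
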