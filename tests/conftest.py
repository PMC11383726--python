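import numpy as np
import pandas as pd
import pytest

from mrlink.gwas_io import HarmonizedInstrumentSet, SummaryStatRecord, SummaryStatTable


def make_record(snp_id="rs1", effect_allele="A", other_allele="G", eaf=0.3,
                beta=0.2, se=0.02, pval=None, n=10_000.0, locus=1_000_000.0):
    """A valid summary record with the p-value consistent with beta/se."""
    if pval is None:
        from scipy import stats
        pval = float(np.clip(2 * stats.norm.sf(abs(beta) / se), np.finfo(float).tiny, 1.0))
    return SummaryStatRecord(snp_id, effect_allele, other_allele, eaf, beta, se, pval, n, locus)


def make_hset(bx, by, sy, sx=None, exposure="X", outcome="Y"):
    """Harmonized set straight from effect arrays."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    rows = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(len(bx))],
        "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy,
        "eaf_exp": np.full_like(bx, 0.3),
    })
    return HarmonizedInstrumentSet(exposure, outcome, rows)


@pytest.fixture
def small_table():
    records = [
        make_record("rs1", "A", "G", 0.3, 0.25, 0.02, locus=1e6),
        make_record("rs2", "C", "T", 0.4, -0.30, 0.025, locus=3e7),
        make_record("rs3", "G", "A", 0.2, 0.40, 0.03, locus=6e7),
    ]
    return SummaryStatTable("cytokine", "continuous", records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240906)


pytest_plugins = []
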