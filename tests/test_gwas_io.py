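"""Summary-statistics IO and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrlink.exceptions import InputError, NoInstrumentsError
from mrlink.gwas_io import (
    FINNGEN_COLUMN_MAP,
    SummaryStatTable,
    harmonize,
    read_summary_stats,
    write_summary_stats,
)

from conftest import make_record


class TestReadWrite:
    def test_identity_read(self, tmp_path, small_table):
        path = tmp_path / "stats.tsv"
        write_summary_stats(small_table, path)
        back = read_summary_stats(path, trait_type="continuous", trait_name="cytokine")
        assert len(back) == 3
        assert [r.snp_id for r in back] == ["rs1", "rs2", "rs3"]

    def test_roundtrip_full_precision(self, tmp_path, small_table):
        path = tmp_path / "stats.tsv"
        write_summary_stats(small_table, path)
        back = read_summary_stats(path, trait_name="cytokine")
        for orig, rec in zip(small_table, back):
            for attr in ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"):
                assert getattr(orig, attr) == getattr(rec, attr)

    def test_invalid_rows_dropped(self, tmp_path, small_table):
        frame = small_table.to_frame()
        frame.loc[1, "se"] = 0.0       # nonpositive se
        frame.loc[2, "eaf"] = 1.5      # out of range
        path = tmp_path / "bad.tsv"
        frame.to_csv(path, sep="\t", index=False)
        back = read_summary_stats(path)
        assert [r.snp_id for r in back] == ["rs1"]

    def test_finngen_header_roundtrip(self, tmp_path, small_table):
        frame = small_table.to_frame().rename(
            columns={v: k for k, v in {}.items()})
        finngen = frame.rename(columns={
            "snp": "rsids", "effect_allele": "alt", "other_allele": "ref",
            "eaf": "af_alt", "se": "sebeta", "locus": "pos"})
        path = tmp_path / "finngen.tsv"
        finngen.to_csv(path, sep="\t", index=False)
        back = read_summary_stats(path, column_map=FINNGEN_COLUMN_MAP, trait_type="binary")
        out = tmp_path / "canonical.tsv"
        write_summary_stats(back, out)
        again = read_summary_stats(out, trait_type="binary")
        assert back.to_frame().drop(columns="locus").equals(again.to_frame().drop(columns="locus"))

    def test_comma_delimiter_autodetected(self, tmp_path, small_table):
        path = tmp_path / "stats.csv"
        small_table.to_frame().to_csv(path, index=False)
        back = read_summary_stats(path)
        assert len(back) == 3

    def test_missing_column_fatal(self, tmp_path, small_table):
        frame = small_table.to_frame().drop(columns=["beta"])
        path = tmp_path / "noeffect.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(InputError, match="beta"):
            read_summary_stats(path)

    def test_empty_file_fatal(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(InputError):
            read_summary_stats(path)

    def test_duplicate_snp_rejected(self):
        recs = [make_record("rs1"), make_record("rs1")]
        with pytest.raises(InputError, match="duplicate"):
            SummaryStatTable("x", "continuous", recs)

    def test_pval_inconsistency_warns_not_drops(self, tmp_path, small_table, caplog):
        frame = small_table.to_frame()
        frame.loc[0, "pval"] = 0.9  # wildly inconsistent with |beta/se| ~ 12
        path = tmp_path / "warn.tsv"
        frame.to_csv(path, sep="\t", index=False)
        import logging
        with caplog.at_level(logging.WARNING):
            back = read_summary_stats(path)
        assert len(back) == 3
        assert any("inconsistent" in r.message for r in caplog.records)


def _one_snp_table(name, trait_type, ea, oa, beta, eaf, se=0.02):
    return SummaryStatTable(name, trait_type, [
        make_record("rs1", ea, oa, eaf, beta, se)])


class TestHarmonize:
    def test_identical_orientation_kept(self):
        exp = _one_snp_table("X", "continuous", "A", "G", 0.1, 0.3)
        out = _one_snp_table("Y", "binary", "A", "G", 0.05, 0.3)
        h = harmonize(exp, out)
        assert h.nsnp == 1
        assert h.rows.loc[0, "beta_out"] == 0.05

    def test_swapped_alleles_negate(self):
        exp = _one_snp_table("X", "continuous", "A", "G", 0.1, 0.3)
        out = _one_snp_table("Y", "binary", "G", "A", 0.05, 0.7)
        h = harmonize(exp, out)
        assert h.rows.loc[0, "beta_out"] == -0.05

    def test_complementary_strand_kept(self):
        exp = _one_snp_table("X", "continuous", "A", "G", 0.1, 0.3)
        out = _one_snp_table("Y", "binary", "T", "C", 0.05, 0.3)
        h = harmonize(exp, out)
        assert h.rows.loc[0, "beta_out"] == 0.05

    def test_complementary_swapped_negates(self):
        exp = _one_snp_table("X", "continuous", "A", "G", 0.1, 0.3)
        out = _one_snp_table("Y", "binary", "C", "T", 0.05, 0.7)
        h = harmonize(exp, out)
        assert h.rows.loc[0, "beta_out"] == -0.05

    def test_palindromic_ambiguous_dropped(self):
        exp = _one_snp_table("X", "continuous", "A", "T", 0.1, 0.50)
        out = _one_snp_table("Y", "binary", "A", "T", 0.05, 0.50)
        exp.records.append(make_record("rs2", "A", "G", 0.2, 0.3))
        out.records.append(make_record("rs2", "A", "G", 0.2, 0.1))
        h = harmonize(exp, out, palindrome_eaf_window=0.08)
        assert ("rs1", "palindromic-ambiguous") in h.dropped
        assert list(h.rows["snp"]) == ["rs2"]

    def test_palindromic_resolved_by_eaf(self):
        # both EAFs well below 0.5: same strand, kept as-is
        exp = _one_snp_table("X", "continuous", "A", "T", 0.1, 0.2)
        out = _one_snp_table("Y", "binary", "A", "T", 0.05, 0.25)
        h = harmonize(exp, out)
        assert h.rows.loc[0, "beta_out"] == 0.05
        # EAFs on opposite sides: other strand, sign flips
        out2 = _one_snp_table("Y", "binary", "A", "T", 0.05, 0.75)
        h2 = harmonize(exp, out2)
        assert h2.rows.loc[0, "beta_out"] == -0.05

    def test_not_found_dropped_and_empty_raises(self):
        exp = _one_snp_table("X", "continuous", "A", "G", 0.1, 0.3)
        out = _one_snp_table("Y", "binary", "A", "G", 0.05, 0.3)
        out.records[0].snp_id = "rs999"
        with pytest.raises(NoInstrumentsError):
            harmonize(exp, out)

    def test_allele_mismatch_dropped(self):
        exp = _one_snp_table("X", "continuous", "A", "G", 0.1, 0.3)
        out = _one_snp_table("Y", "binary", "A", "C", 0.05, 0.3)
        with pytest.raises(NoInstrumentsError):
            harmonize(exp, out)

    def test_idempotent(self, small_table):
        outcome = SummaryStatTable("Y", "binary", [
            make_record(r.snp_id, r.effect_allele, r.other_allele, r.eaf, r.beta * 0.5, 0.05)
            for r in small_table
        ])
        h1 = harmonize(small_table, outcome)
        # rebuild an outcome already on the exposure orientation
        aligned = SummaryStatTable("Y", "binary", [
            make_record(row["snp"], rec.effect_allele, rec.other_allele,
                        rec.eaf, row["beta_out"], row["se_out"])
            for (_, row), rec in zip(h1.rows.iterrows(), small_table)
        ])
        h2 = harmonize(small_table, aligned)
        pd.testing.assert_frame_equal(h1.rows, h2.rows)

    @given(st.lists(
        st.tuples(st.floats(-0.5, 0.5), st.floats(0.05, 0.95)),
        min_size=1, max_size=8, unique_by=lambda t: t))
    @settings(max_examples=25, deadline=None)
    def test_swap_roundtrip(self, effects):
        """Swapping outcome alleles and negating beta, then harmonizing,
        reproduces the original harmonized rows."""
        exp = SummaryStatTable("X", "continuous", [
            make_record(f"rs{i}", "A", "G", 0.3, 0.2 + 0.01 * i) for i in range(len(effects))])
        out = SummaryStatTable("Y", "binary", [
            make_record(f"rs{i}", "A", "G", eaf, beta if beta != 0 else 0.01)
            for i, (beta, eaf) in enumerate(effects)])
        swapped = SummaryStatTable("Y", "binary", [
            make_record(r.snp_id, r.other_allele, r.effect_allele, 1 - r.eaf, -r.beta, r.se)
            for r in out])
        h1 = harmonize(exp, out)
        h2 = harmonize(exp, swapped)
        pd.testing.assert_frame_equal(h1.rows, h2.rows)
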