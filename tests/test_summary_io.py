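"""Summary-statistic reading, validation, and allele harmonization."""
import logging

import pytest

from summarymr import (
    HarmonizationError,
    SummaryStatsError,
    VariantAssociation,
    datasets,
    harmonize,
    harmonize_tables,
    read_summary_stats,
    write_summary_stats,
)

CRP_DIALECT = {"beta": "beta_crp", "se": "se_crp", "pvalue": "p_crp"}


def _assoc(**kw):
    base = dict(
        variant_id="rs1", chrom="1", pos=100, effect_allele="T", other_allele="C",
        eaf=0.4, beta=0.1, se=0.05, pvalue=0.01,
    )
    base.update(kw)
    return VariantAssociation(**base)


class TestRead:
    def test_fixture_table_round(self):
        recs = read_summary_stats(datasets.crp_t2dm_path(), dialect=CRP_DIALECT)
        assert len(recs) == 5
        first = recs[0]
        assert first.variant_id == "rs6700896"
        assert (first.chrom, first.pos) == ("1", 65862370)
        assert first.beta == -0.147 and first.se == 0.01429
        assert first.pvalue == 1.6e-21
        assert [r.variant_id for r in recs][-1] == "rs4420638"  # order preserved

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("snp\tchr\tbp\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\n")
        assert read_summary_stats(p) == []

    def test_zero_se_row_rejected_with_row_diagnostic(self, tmp_path, caplog):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "snp\tchr\tbp\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\n"
            "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.05\t0.01\n"
            "rs2\t1\t200\tA\tG\t0.2\t0.1\t0\t0.01\n"
        )
        with caplog.at_level(logging.WARNING):
            recs = read_summary_stats(p)
        assert [r.variant_id for r in recs] == ["rs1"]
        assert any("row 3" in m and "rs2" in m for m in caplog.messages)
        with pytest.raises(SummaryStatsError, match="row 3"):
            read_summary_stats(p, on_invalid="raise")

    def test_unparseable_numeric_reports_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "snp\tchr\tbp\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\n"
            "rs1\t1\t100\tA\tG\t0.2\tnot_a_number\t0.05\t0.01\n"
        )
        with pytest.raises(SummaryStatsError, match="row 2"):
            read_summary_stats(p)

    def test_missing_column_and_missing_file(self, tmp_path):
        p = tmp_path / "cols.tsv"
        p.write_text("snp\tchr\n")
        with pytest.raises(SummaryStatsError, match="missing required column"):
            read_summary_stats(p)
        with pytest.raises(FileNotFoundError):
            read_summary_stats(tmp_path / "absent.tsv")

    def test_missing_eaf_tolerated(self, tmp_path):
        p = tmp_path / "na.tsv"
        p.write_text(
            "snp\tchr\tbp\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\n"
            "rs1\t1\t100\tA\tG\t.\t0.1\t0.05\t0.01\n"
        )
        (rec,) = read_summary_stats(p)
        assert rec.eaf is None

    def test_write_read_round_trip_bit_identical(self, tmp_path):
        recs = read_summary_stats(datasets.crp_t2dm_path(), dialect=CRP_DIALECT)
        recs.append(_assoc(variant_id="rs_missing_eaf", eaf=None))
        out = tmp_path / "roundtrip.tsv"
        write_summary_stats(recs, out)
        back = read_summary_stats(out)
        assert back == recs


class TestValidation:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("se", -1.0), ("se", 0.0), ("pvalue", 0.0), ("pvalue", 1.5),
            ("eaf", 1.0), ("beta", float("nan")), ("other_allele", "T"),
            ("effect_allele", "N"),
        ],
    )
    def test_invariant_violations_raise(self, field, value):
        with pytest.raises(ValueError):
            _assoc(**{field: value})


class TestHarmonize:
    def test_matching_alleles_copied_unchanged(self):
        exp = _assoc(variant_id="rs6700896", beta=-0.147)
        out = _assoc(variant_id="rs6700896", beta=-0.00995, se=0.01493, pvalue=0.41)
        h = harmonize(exp, out)
        assert not h.flipped
        assert h.beta_exposure == -0.147 and h.beta_outcome == -0.00995

    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = _assoc(beta=-0.147)
        out = _assoc(effect_allele="C", other_allele="T", beta=0.00995, eaf=0.62)
        h = harmonize(exp, out)
        assert h.flipped
        assert h.beta_outcome == -0.00995
        assert h.eaf_outcome == pytest.approx(0.38)

    def test_idempotent_on_aligned_pair(self):
        exp = _assoc(beta=-0.147)
        out = _assoc(beta=-0.00995, se=0.01493, pvalue=0.41)
        h1 = harmonize(exp, out)
        realigned = _assoc(beta=h1.beta_outcome, se=h1.se_outcome, pvalue=h1.p_outcome)
        assert harmonize(exp, realigned) == h1

    def test_id_mismatch_and_incompatible_alleles(self):
        with pytest.raises(HarmonizationError, match="mismatch"):
            harmonize(_assoc(variant_id="rs1"), _assoc(variant_id="rs2"))
        with pytest.raises(HarmonizationError, match="incompatible"):
            harmonize(_assoc(), _assoc(effect_allele="A", other_allele="G"))

    @pytest.mark.parametrize("policy, expect", [("keep", "kept"), ("drop", None)])
    def test_palindrome_policies(self, policy, expect, caplog):
        exp = _assoc(effect_allele="A", other_allele="T")
        out = _assoc(effect_allele="A", other_allele="T")
        with caplog.at_level(logging.INFO):
            h = harmonize(exp, out, palindrome_policy=policy)
        if expect is None:
            assert h is None
        else:
            assert h is not None
            assert any("palindromic" in m for m in caplog.messages)

    def test_palindrome_error_policy(self):
        exp = _assoc(effect_allele="C", other_allele="G")
        out = _assoc(effect_allele="C", other_allele="G")
        with pytest.raises(HarmonizationError, match="palindromic"):
            harmonize(exp, out, palindrome_policy="error")


class TestHarmonizeTables:
    def test_one_sided_variants_excluded_not_errors(self):
        exp = [_assoc(variant_id="rs1"), _assoc(variant_id="rs2")]
        out = [_assoc(variant_id="rs2"), _assoc(variant_id="rs3")]
        kept, dropped = harmonize_tables(exp, out)
        assert [h.variant_id for h in kept] == ["rs2"]
        assert {d[0] for d in dropped} == {"rs1", "rs3"}

    def test_fixture_tables_fully_harmonize(self):
        kept, dropped = harmonize_tables(*datasets.crp_t2dm_associations())
        assert len(kept) == 5 and dropped == []
        assert all(not h.flipped for h in kept)
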