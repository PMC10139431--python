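"""Instrument construction: SE reconstruction, masking, harmonization, clumping, I/O."""
import math

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mrkit import (
    EXTENDED_HLA_REGION,
    AssociationRecord,
    GenomicRegion,
    HarmonizationRejection,
    LDMatrix,
    filter_region,
    harmonize,
    is_palindromic,
    pval_from_beta_se,
    read_summary_tsv,
    se_from_pval,
    select_instruments,
    write_summary_tsv,
)
from mrkit.summary_data import records_in_region
from mrkit.synthetic import generate_ld_blocks

MATURE_TNK = "Mature T/NK-cell lymphomas"


def rec(snp="rs1", chrom=1, pos=1000, ea="C", oa="T", beta=0.1, pval=1e-9, **kw):
    return AssociationRecord(snp, chrom, pos, ea, oa, beta, pval, **kw)


class TestSeFromPval:
    @pytest.mark.parametrize(
        "beta, pval, expected",
        [
            (-0.267, 2.33e-2, 0.1177),  # rs1738074 outcome association
            (1.959964, 0.05, 1.0),
            (-0.3239, 6.31e-18, 0.0376),  # rs13151961 exposure association
        ],
    )
    def test_reconstruction(self, beta, pval, expected):
        assert se_from_pval(beta, pval) == pytest.approx(expected, rel=2e-3)

    @pytest.mark.parametrize("pval", [0.0, 1.0, 1.5, -0.1])
    def test_out_of_range_pval(self, pval):
        with pytest.raises(ValueError):
            se_from_pval(0.5, pval)

    def test_zero_beta_degenerate(self):
        with pytest.raises(ValueError):
            se_from_pval(0.0, 0.5)

    def test_underflowing_pval_refused(self):
        with pytest.raises(ValueError, match="supply the SE"):
            se_from_pval(0.5, 1e-310)

    @settings(max_examples=200, derandomize=True)
    @given(
        beta=st.floats(0.001, 10.0),
        pval=st.floats(1e-250, 0.999),
    )
    def test_inverse_of_two_sided_pval(self, beta, pval):
        se = se_from_pval(beta, pval)
        assert pval_from_beta_se(beta, se) == pytest.approx(pval, rel=1e-10)


class TestRegionFilter:
    def test_table1_snps_outside_hla_retained(self):
        kept = filter_region(
            [
                rec("rs1738074", 6, 159_465_977),
                rec("rs2327832", 6, 138_006_504),
            ],
            EXTENDED_HLA_REGION,
        )
        assert [r.snp_id for r in kept] == ["rs1738074", "rs2327832"]

    def test_midpoint_of_mask_removed(self):
        assert filter_region([rec("rsX", 6, 30_000_000)], EXTENDED_HLA_REGION) == []

    def test_boundaries_inclusive(self):
        inside = [rec("a", 6, 20_000_000), rec("b", 6, 40_000_000)]
        assert filter_region(inside, EXTENDED_HLA_REGION) == []

    def test_partition(self, exposure_records):
        region = GenomicRegion(2, 1, 200_000_000)
        outside = filter_region(exposure_records, region)
        inside = records_in_region(exposure_records, region)
        assert sorted(r.snp_id for r in outside + inside) == sorted(
            r.snp_id for r in exposure_records
        )
        assert not {r.snp_id for r in outside} & {r.snp_id for r in inside}


class TestPalindromy:
    @pytest.mark.parametrize(
        "a1, a2, expected",
        [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
         ("T", "C", False), ("A", "G", False), ("A", "C", False)],
    )
    def test_pairs(self, a1, a2, expected):
        assert is_palindromic(a1, a2) is expected

    def test_invalid_allele(self):
        with pytest.raises(ValueError):
            is_palindromic("A", "N")


class TestHarmonize:
    def test_co_oriented_pair_copied(self):
        exp = rec("rs1738074", 6, 159_465_977, "C", "T", -0.1424, 3.14e-8)
        out = rec("rs1738074", 6, 159_465_977, "C", "T", -0.267, 2.33e-2)
        inst = harmonize(exp, out)
        assert not inst.flipped
        assert inst.beta_out == -0.267
        assert inst.beta_exp == -0.1424

    def test_label_swap_negates(self):
        exp = rec("rs1738074", 6, 1, "C", "T", -0.1424, 3.14e-8)
        out = rec("rs1738074", 6, 1, "T", "C", 0.267, 2.33e-2, eaf=0.4)
        inst = harmonize(exp, out)
        assert inst.flipped
        assert inst.beta_out == pytest.approx(-0.267)
        assert inst.eaf_out == pytest.approx(0.6)

    def test_double_swap_is_involution(self):
        exp = rec("rs1", 1, 1, "C", "T", 0.2, 1e-9)
        out = rec("rs1", 1, 1, "T", "C", 0.3, 1e-3)
        once = harmonize(exp, out)
        # re-expressing the already-aligned outcome and harmonizing again is a no-op
        realigned = rec("rs1", 1, 1, "C", "T", once.beta_out, 1e-3)
        twice = harmonize(exp, realigned)
        assert twice.beta_out == pytest.approx(once.beta_out)
        assert not twice.flipped

    def test_strand_complement_rescue(self):
        exp = rec("rs1", 1, 1, "C", "T", 0.2, 1e-9)
        out = rec("rs1", 1, 1, "G", "A", 0.3, 1e-3)  # other strand, same orientation
        inst = harmonize(exp, out)
        assert not inst.flipped
        assert inst.beta_out == 0.3

    def test_ambiguous_palindrome_rejected(self):
        exp = rec("rs1", 1, 1, "A", "T", 0.2, 1e-9)
        out = rec("rs1", 1, 1, "A", "T", 0.3, 1e-3, eaf=0.50)
        result = harmonize(exp, out, drop_palindromic=True)
        assert isinstance(result, HarmonizationRejection)

    def test_extreme_frequency_palindrome_kept(self):
        exp = rec("rs1", 1, 1, "A", "T", 0.2, 1e-9)
        out = rec("rs1", 1, 1, "A", "T", 0.3, 1e-3, eaf=0.05)
        result = harmonize(exp, out, drop_palindromic=True, ambiguity_maf=0.3)
        assert not isinstance(result, HarmonizationRejection)

    def test_mismatched_snp_id_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            harmonize(rec("rs1"), rec("rs2"))

    def test_unresolvable_alleles_rejected(self):
        exp = rec("rs1", 1, 1, "C", "T", 0.2, 1e-9)
        out = rec("rs1", 1, 1, "C", "A", 0.3, 1e-3)
        result = harmonize(exp, out)
        assert isinstance(result, HarmonizationRejection)
        assert "unresolvable" in result.reason


class TestClumping:
    def test_independent_snps_all_kept(self):
        recs = [rec(f"rs{i}", 1, 1000 * i, pval=1e-10) for i in range(1, 4)]
        assert len(select_instruments(recs)) == 3

    def test_greedy_rule_keeps_smaller_p(self):
        a = rec("rsA", 1, 1_000_000, pval=1e-10)
        b = rec("rsB", 1, 2_000_000, pval=1e-9)
        ld = LDMatrix({frozenset(("rsA", "rsB")): 0.5})
        kept = select_instruments([a, b], ld=ld, r2_max=0.001, window_bp=5_000_000)
        assert [r.snp_id for r in kept] == ["rsA"]

    def test_window_limits_ld_reach(self):
        a = rec("rsA", 1, 1_000_000, pval=1e-10)
        b = rec("rsB", 1, 20_000_000, pval=1e-9)  # same chrom, outside window
        ld = LDMatrix({frozenset(("rsA", "rsB")): 0.9})
        assert len(select_instruments([a, b], ld=ld)) == 2

    def test_p_threshold(self):
        recs = [rec("rsA", 1, 1, pval=1e-10), rec("rsB", 2, 1, pval=1e-7)]
        assert [r.snp_id for r in select_instruments(recs, p_threshold=5e-8)] == ["rsA"]

    def test_study_instruments_all_independent(self, exposure_records):
        kept = select_instruments(exposure_records, p_threshold=5e-8)
        assert len(kept) == 11

    @pytest.mark.parametrize(
        "n_blocks, per_block, r2_within, expected",
        [(5, 4, 0.8, 5), (3, 4, 0.0, 12), (1, 1, 0.5, 1)],
    )
    def test_block_structure(self, n_blocks, per_block, r2_within, expected):
        recs, ld = generate_ld_blocks(n_blocks, per_block, r2_within, seed=7)
        kept = select_instruments(recs, ld=ld, r2_max=0.001, window_bp=5_000_000)
        assert len(kept) == expected
        # no kept same-chromosome pair within the window exceeds the threshold
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                if a.chrom == b.chrom and abs(a.pos_bp - b.pos_bp) <= 5_000_000:
                    assert ld.r2(a.snp_id, b.snp_id) <= 0.001


class TestTsvIO:
    def test_roundtrip_identity(self, exposure_records, tmp_path):
        path = tmp_path / "exp.tsv"
        write_summary_tsv(exposure_records, path)
        back = read_summary_tsv(path)
        assert back == exposure_records

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(
            "snp\tchr\tpos\teffect_allele\tother_allele\tbeta\tse\tpval\teaf\ttrait\n"
        )
        assert read_summary_tsv(path) == []

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("snp\tchr\tpos\tbeta\tpval\n")
        with pytest.raises(ValueError, match="missing mandatory"):
            read_summary_tsv(path)

    def test_bad_numeric_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "snp\tchr\tpos\teffect_allele\tother_allele\tbeta\tse\tpval\teaf\ttrait\n"
            "rs1\t1\t100\tA\tG\tnot_a_number\t\t0.5\t\tx\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            read_summary_tsv(path)

    def test_column_map(self, tmp_path):
        path = tmp_path / "alt.tsv"
        path.write_text("rsid\tCHR\tBP\tA1\tA2\tBETA\tP\nrs1\t1\t100\tA\tG\t0.2\t1e-9\n")
        recs = read_summary_tsv(
            path,
            column_map={
                "snp": "rsid", "chr": "CHR", "pos": "BP", "effect_allele": "A1",
                "other_allele": "A2", "beta": "BETA", "pval": "P",
                "se": None, "eaf": None, "trait": None,
            },
        )
        assert recs[0].beta == 0.2


class TestPackagedFixture:
    def test_shape(self, table1):
        outcomes = [t for t in table1 if t != "Celiac disease"]
        assert len(outcomes) == 8
        for trait in outcomes:
            ids = [r.snp_id for r in table1[trait]]
            assert len(ids) == 11 and len(set(ids)) == 11
        assert len(table1["Celiac disease"]) == 11

    def test_proxy_parenthetical_parsed(self, table1):
        by_id = {r.snp_id: r for r in table1[MATURE_TNK]}
        assert "rs2327832" in by_id
        assert by_id["rs2327832"].proxy_id == "rs6920220"

    def test_no_palindromic_instruments(self, table1):
        for r in table1["Celiac disease"]:
            assert not is_palindromic(r.effect_allele, r.other_allele)

    def test_harmonization_keeps_all_eleven(self, tnk_instruments):
        assert len(tnk_instruments) == 11
        assert all(not i.flipped for i in tnk_instruments)
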