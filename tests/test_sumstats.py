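"""Summary-statistic reading, validation, and harmonization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netmr.sumstats import (
    COMPLEMENT,
    SummaryStatRecord,
    SummaryStatTable,
    SumstatError,
    TraitMeta,
    HarmonizeError,
    harmonize,
    read_sumstats,
)

META = TraitMeta("trait_a", "continuous", n=10_000)


def _write(tmp_path, text, name="ss.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "snp\tchr\tpos\tea\toa\teaf\tbeta\tse\tpval\tn\n"


class TestReadSumstats:
    def test_well_formed_round_trip(self, tmp_path):
        p = _write(
            tmp_path,
            HEADER
            + "rs1\t1\t100\tA\tG\t0.2\t0.10\t0.01\t1e-9\t10000\n"
            + "rs2\t2\t200\tC\tT\t0.4\t-0.05\t0.02\t1e-8\t10000\n"
            + "rs3\t3\t300\tG\tA\t0.1\t0.02\t0.01\t0.5\t10000\n",
        )
        table = read_sumstats(p, META)
        assert len(table) == 3
        assert table.get("rs2").beta == -0.05
        # writing and re-reading preserves every record
        out = tmp_path / "round.tsv"
        table.write(out)
        again = read_sumstats(out, META)
        assert [r.snp_id for r in again.records] == ["rs1", "rs2", "rs3"]
        assert again.get("rs1").eaf == pytest.approx(0.2)

    def test_nonpositive_se_rejected_with_reason(self, tmp_path):
        p = _write(
            tmp_path,
            HEADER
            + "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.0\t1e-9\t10000\n"
            + "rs2\t1\t200\tA\tG\t0.2\t0.1\t0.01\t1e-9\t10000\n",
        )
        table = read_sumstats(p, META)
        assert len(table) == 1
        assert table.rejections == [("rs1", "nonpositive SE")]

    def test_lowercase_alleles_normalized(self, tmp_path):
        p = _write(
            tmp_path,
            HEADER
            + "rs1\t1\t100\ta\tg\t0.2\t0.1\t0.01\t1e-9\t10000\n"
            + "rs2\t1\t200\tc\tt\t0.2\t0.1\t0.01\t1e-9\t10000\n"
            + "rs3\t1\t300\tg\ta\t0.2\t0.1\t0.01\t1e-9\t10000\n",
        )
        table = read_sumstats(p, META)
        assert len(table) == 3
        assert [(r.effect_allele, r.other_allele) for r in table.records] == [
            ("A", "G"), ("C", "T"), ("G", "A"),
        ]

    def test_column_map_and_missing_column(self, tmp_path):
        p = _write(tmp_path, "rsid,A1,A2,b,stderr,p\nrs1,A,G,0.1,0.01,1e-9\n", "ss.csv")
        table = read_sumstats(
            p, META,
            column_map={"snp": "rsid", "ea": "A1", "oa": "A2",
                        "beta": "b", "se": "stderr", "pval": "p"},
        )
        assert table.get("rs1").n == 10_000  # filled from trait meta
        with pytest.raises(SumstatError, match="missing required column"):
            read_sumstats(p, META)

    def test_zero_valid_rows_is_an_error(self, tmp_path):
        p = _write(tmp_path, HEADER + "rs1\t1\t100\tA\tA\t0.2\t0.1\t0.01\t1e-9\t100\n")
        with pytest.raises(SumstatError, match="zero valid rows"):
            read_sumstats(p, META)


def _rec(snp, ea, oa, beta, eaf=0.3, se=0.01, pval=1e-9):
    return SummaryStatRecord(snp, ea, oa, beta, se, pval, chrom="1",
                             pos=100, eaf=eaf, n=1000)


def _table(trait, recs):
    return SummaryStatTable(trait, "continuous", recs)


class TestHarmonize:
    def test_swapped_alleles_flip_the_outcome_beta(self):
        exp = _table("e", [_rec("rs1", "A", "G", 0.10)])
        out = _table("o", [_rec("rs1", "G", "A", -0.05, eaf=0.7)])
        h = harmonize(exp, out)
        (pair,) = h.pairs
        assert pair.status == "flipped"
        assert pair.beta_out == pytest.approx(0.05)
        assert pair.eaf_out == pytest.approx(0.3)

    def test_palindromic_dropped_under_drop_policy(self):
        exp = _table("e", [_rec("rs1", "A", "T", 0.1), _rec("rs2", "A", "G", 0.1)])
        out = _table("o", [_rec("rs1", "A", "T", 0.1), _rec("rs2", "A", "G", 0.1)])
        h = harmonize(exp, out, palindrome_policy="drop")
        assert h.dropped == {"rs1": "dropped_palindromic"}
        assert [p.snp_id for p in h.pairs] == ["rs2"]

    def test_strand_flip_translated_then_aligned(self):
        # exposure C/T vs outcome G/A is the complementary strand
        exp = _table("e", [_rec("rs1", "C", "T", 0.1)])
        out = _table("o", [_rec("rs1", "G", "A", 0.02)])
        (pair,) = harmonize(exp, out).pairs
        assert pair.status == "strand_flipped"
        assert pair.beta_out == pytest.approx(0.02)

    def test_strand_flip_with_swap_negates(self):
        exp = _table("e", [_rec("rs1", "C", "T", 0.1)])
        out = _table("o", [_rec("rs1", "A", "G", 0.02, eaf=0.8)])
        (pair,) = harmonize(exp, out).pairs
        assert pair.status == "strand_flipped"
        assert pair.beta_out == pytest.approx(-0.02)
        assert pair.eaf_out == pytest.approx(0.2)

    def test_palindromic_inference_by_eaf(self):
        # frequencies agree -> kept as-is; disagree -> flipped
        exp = _table("e", [_rec("rs1", "A", "T", 0.1, eaf=0.1),
                           _rec("rs2", "C", "G", 0.1, eaf=0.1)])
        out = _table("o", [_rec("rs1", "A", "T", 0.05, eaf=0.12),
                           _rec("rs2", "C", "G", 0.05, eaf=0.9)])
        h = harmonize(exp, out, palindrome_policy="infer_by_eaf")
        by_id = {p.snp_id: p for p in h.pairs}
        assert by_id["rs1"].status == "kept"
        assert by_id["rs1"].beta_out == pytest.approx(0.05)
        assert by_id["rs2"].status == "flipped"
        assert by_id["rs2"].beta_out == pytest.approx(-0.05)

    def test_palindromic_near_half_or_missing_eaf_always_dropped(self):
        exp = _table("e", [_rec("rs1", "A", "T", 0.1, eaf=0.47),
                           _rec("rs2", "C", "G", 0.1, eaf=None)])
        out = _table("o", [_rec("rs1", "A", "T", 0.05, eaf=0.2),
                           _rec("rs2", "C", "G", 0.05, eaf=0.2)])
        h = harmonize(exp, out, palindrome_policy="infer_by_eaf", eaf_window=0.08)
        assert h.dropped == {"rs1": "dropped_palindromic",
                             "rs2": "dropped_palindromic"}

    def test_incompatible_alleles_dropped(self):
        exp = _table("e", [_rec("rs1", "A", "G", 0.1)])
        out = _table("o", [_rec("rs1", "A", "C", 0.1)])
        h = harmonize(exp, out)
        assert h.dropped == {"rs1": "dropped_incompatible"}

    def test_same_trait_and_empty_intersection_errors(self):
        t1 = _table("e", [_rec("rs1", "A", "G", 0.1)])
        t2 = _table("o", [_rec("rs9", "A", "G", 0.1)])
        with pytest.raises(HarmonizeError, match="same trait"):
            harmonize(t1, t1)
        with pytest.raises(HarmonizeError, match="no shared SNPs"):
            harmonize(t1, t2)

    def test_count_identity(self):
        exp = _table("e", [
            _rec("rs1", "A", "G", 0.1), _rec("rs2", "A", "T", 0.1),
            _rec("rs3", "C", "T", 0.1), _rec("rs4", "A", "G", 0.1),
        ])
        out = _table("o", [
            _rec("rs1", "G", "A", 0.1), _rec("rs2", "A", "T", 0.1),
            _rec("rs3", "G", "A", 0.1), _rec("rs4", "A", "C", 0.1),
        ])
        h = harmonize(exp, out)
        counts = h.provenance["counts"]
        assert sum(counts.values()) == h.provenance["n_shared"] == 4
        assert len(h.pairs) + len(h.dropped) == 4


ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


@given(
    e_alleles=st.sampled_from(ALLELE_PAIRS),
    swap=st.booleans(),
    strand=st.booleans(),
    beta=st.floats(-1, 1, allow_nan=False),
    eaf=st.floats(0.05, 0.95),
)
def test_harmonize_is_idempotent_and_double_swap_restores(e_alleles, swap, strand, beta, eaf):
    """Harmonizing an already-harmonized pair changes nothing, and a
    double allele swap restores the original outcome beta exactly."""
    ea, oa = e_alleles
    o_ea, o_oa, o_beta, o_eaf = ea, oa, beta, eaf
    if swap:
        o_ea, o_oa, o_beta, o_eaf = oa, ea, -beta, 1 - eaf
    if strand:
        o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
    exp = _table("e", [_rec("rs1", ea, oa, 0.1, eaf=eaf)])
    out = _table("o", [_rec("rs1", o_ea, o_oa, o_beta, eaf=o_eaf)])
    h1 = harmonize(exp, out, palindrome_policy="drop")
    if COMPLEMENT[ea] == oa:
        assert h1.dropped.get("rs1") == "dropped_palindromic"
        return
    (p1,) = h1.pairs
    assert p1.beta_out == pytest.approx(beta)  # double swap restores
    # idempotence: re-harmonize the aligned output against the exposure
    out2 = _table("o", [_rec("rs1", p1.effect_allele, p1.other_allele,
                             p1.beta_out, eaf=p1.eaf_out)])
    (p2,) = harmonize(exp, out2).pairs
    assert p2.status == "kept"
    assert p2.beta_out == p1.beta_out
    assert p2.eaf_out == pytest.approx(p1.eaf_out)
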