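"""Per-gene selection rules, fold-change semantics and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deapr import (
    ComparisonResult,
    DEGeneRecord,
    ExpressionMatrix,
    GeneAnnotation,
    SampleSet,
    delv_test,
    floored,
    prefilter,
    rank_genes,
    select_de_genes,
    signed_ratio,
    srmm_test,
)
from deapr.errors import ValidationError

CODING = {"biotype": "protein_coding"}


def _one_gene_matrix(ref_vals, test_vals):
    samples = [f"R{i}" for i in range(len(ref_vals))] + [f"T{i}" for i in range(len(test_vals))]
    frame = pd.DataFrame([list(ref_vals) + list(test_vals)], index=["G1"], columns=samples)
    matrix = ExpressionMatrix(frame)
    ref = SampleSet("ref", tuple(f"R{i}" for i in range(len(ref_vals))))
    test = SampleSet("test", tuple(f"T{i}" for i in range(len(test_vals))))
    ann = GeneAnnotation({"G1": ("G1", "protein_coding")})
    return matrix, ann, ref, test


class TestFlooring:
    @pytest.mark.parametrize("value,floor,expected", [
        (0.0, 0.01, 0.01),   # zero FPKM becomes the minimum detectable level
        (5.0, 0.01, 5.0),
        (0.005, 0.01, 0.01),
    ])
    def test_floored(self, value, floor, expected):
        assert floored(value, floor) == expected

    def test_floor_must_be_positive(self):
        with pytest.raises(ValidationError):
            floored(1.0, 0.0)

    @pytest.mark.parametrize("ref,test,expected", [
        (2.0, 8.0, 4.0),
        (8.0, 2.0, -4.0),
        (0.0, 5.0, 500.0),   # 5 / 0.01 by the floor rule
    ])
    def test_signed_ratio(self, ref, test, expected):
        assert signed_ratio(ref, test, 0.01) == pytest.approx(expected)

    def test_signed_ratio_magnitude_at_least_one(self):
        for ref, test in [(3.0, 3.0), (1.0, 1.5), (1.5, 1.0)]:
            assert abs(signed_ratio(ref, test, 0.01)) >= 1.0


class TestDelv:
    def test_clean_fold_change_selected(self):
        out = delv_test([10, 11, 12], [40, 44, 42], 0.01)
        assert out.eligible and out.selected
        assert out.signed_fc == pytest.approx(42 / 11)
        assert out.fpkm_diff == pytest.approx(31.0)

    def test_noisy_reference_set_not_eligible(self):
        out = delv_test([10, 25, 12], [40, 44, 42], 0.01)
        assert not out.eligible and not out.selected

    def test_small_change_eligible_but_not_selected(self):
        out = delv_test([10, 11, 12], [15, 16, 17], 0.01)
        assert out.eligible and not out.selected
        assert out.signed_fc == pytest.approx(16 / 11)

    def test_boundary_within_set_ratio_exactly_two_fails_gate(self):
        # "fewer than two" is strict: a 2.0 range ratio is not low-variability
        out = delv_test([1.0, 2.0], [10.0, 10.0], 0.01)
        assert not out.eligible

    def test_all_zero_set_floors_to_ratio_one_and_passes_gate(self):
        out = delv_test([0.0, 0.0, 0.0], [3.0, 4.0, 5.0], 0.01)
        assert out.eligible and out.selected
        assert out.signed_fc == pytest.approx(4.0 / 0.01)
        assert out.fpkm_diff == pytest.approx(4.0)

    def test_too_few_replicates(self):
        with pytest.raises(ValidationError):
            delv_test([1.0], [2.0, 3.0], 0.01)


class TestSrmm:
    def test_separated_with_outlier_tolerated(self):
        out = srmm_test([1, 2, 3], [8, 30, 9], 0.01)
        assert out.separated and out.selected
        assert out.signed_fc == pytest.approx(8 / 3)
        assert out.fpkm_diff == pytest.approx(5.0)

    def test_overlapping_ranges_never_selected(self):
        out = srmm_test([1, 2, 3], [2.5, 30, 9], 0.01)
        assert not out.separated and not out.selected

    def test_all_zero_test_set_floors(self):
        out = srmm_test([10, 12, 11], [0, 0, 0], 0.01)
        assert out.selected
        assert out.signed_fc == pytest.approx(-10 / 0.01)
        # gap between the nearer extremes: max(test) - min(ref)
        assert out.fpkm_diff == pytest.approx(-10.0)

    def test_separated_but_under_twofold_not_selected(self):
        out = srmm_test([1.0, 1.1], [1.5, 1.6], 0.01)
        assert out.separated and not out.selected

    def test_boundary_separation_exactly_two_selected(self):
        out = srmm_test([1.0, 1.5], [3.0, 4.0], 0.01)
        assert out.selected and out.signed_fc == pytest.approx(2.0)


class TestRanking:
    def test_single_record(self):
        [r] = rank_genes([DEGeneRecord("G1", "G1", "DELV", 4.0, 10.0)])
        assert (r.fc_rank, r.diff_rank, r.final_rank) == (1, 1, 1)
        assert r.combined_rank == pytest.approx(1.0)

    def test_ninety_ten_weighting(self):
        a = DEGeneRecord("A", "A", "DELV", 10.0, 5.0)
        b = DEGeneRecord("B", "B", "DELV", 4.0, 500.0)
        ranked = rank_genes([a, b])
        by_id = {r.gene_id: r for r in ranked}
        assert by_id["A"].combined_rank == pytest.approx(0.9 * 1 + 0.1 * 2)
        assert by_id["B"].combined_rank == pytest.approx(0.9 * 2 + 0.1 * 1)
        assert [r.gene_id for r in ranked] == ["A", "B"]

    def test_deterministic_tie_break_by_gene_id(self):
        recs = [DEGeneRecord(g, g, "DELV", 4.0, 10.0) for g in ("GB", "GA", "GC")]
        ranked = rank_genes(recs)
        assert [r.gene_id for r in ranked] == ["GA", "GB", "GC"]

    @given(st.permutations(range(6)))
    @settings(max_examples=30, deadline=None)
    def test_order_invariance(self, perm):
        recs = [
            DEGeneRecord(f"G{i}", f"G{i}", "DELV",
                         signed_fc=(-1) ** i * (2.0 + i), fpkm_diff=(-1) ** i * (50.0 - 3 * i))
            for i in range(6)
        ]
        baseline = [r.gene_id for r in rank_genes(recs)]
        shuffled = [recs[i] for i in perm]
        assert [r.gene_id for r in rank_genes(shuffled)] == baseline
        # final_rank is a permutation of 1..N
        assert sorted(r.final_rank for r in rank_genes(shuffled)) == list(range(1, 7))


class TestPrefilter:
    @pytest.mark.parametrize("ref,test,biotype,kept", [
        ((0.9, 0.8, 0.7), (0.5, 0.4, 0.3), "protein_coding", False),  # all < 1 FPKM
        ((0.2, 0.2, 0.2), (1.5, 1.4, 1.6), "protein_coding", True),   # one sample >= 1
        ((100, 100, 100), (5, 5, 5), "lincRNA", False),               # biotype screen
    ])
    def test_screen(self, ref, test, biotype, kept):
        matrix, _, ref_set, test_set = _one_gene_matrix(ref, test)
        ann = GeneAnnotation({"G1": ("G1", biotype)})
        assert (prefilter(matrix, ann, ref_set, test_set) == ["G1"]) is kept

    def test_overlapping_sets_rejected(self):
        matrix, ann, ref, _ = _one_gene_matrix([1, 2], [3, 4])
        with pytest.raises(ValidationError, match="overlap"):
            prefilter(matrix, ann, ref, ref)

    def test_unannotated_gene_is_screened_out(self):
        matrix, _, ref, test = _one_gene_matrix([5, 5], [20, 20])
        assert prefilter(matrix, GeneAnnotation({}), ref, test) == []


class TestSelectDeGenes:
    def test_flat_matrix_yields_no_records(self):
        samples = [f"S{i}" for i in range(6)]
        frame = pd.DataFrame(np.full((10, 6), 7.0),
                             index=[f"G{i}" for i in range(10)], columns=samples)
        matrix = ExpressionMatrix(frame)
        ann = GeneAnnotation({f"G{i}": (f"G{i}", "protein_coding") for i in range(10)})
        ref = SampleSet("r", tuple(samples[:3]))
        test = SampleSet("t", tuple(samples[3:]))
        result = select_de_genes(matrix, ann, ref, test)
        assert len(result) == 0 and result.screened_gene_count == 10

    def test_all_zero_reference_traces_delv_path(self):
        matrix, ann, ref, test = _one_gene_matrix([0, 0, 0], [3, 4, 5])
        result = select_de_genes(matrix, ann, ref, test)
        [rec] = result.records
        assert rec.method == "DELV"
        assert rec.signed_fc == pytest.approx(4.0 / 0.01)

    def test_comparison_table_round_trip(self, comp1, tmp_path):
        path = tmp_path / "comp1.tsv"
        comp1.to_tsv(str(path))
        again = ComparisonResult.from_tsv(str(path))
        assert again.gene_ids() == comp1.gene_ids()
        for a, b in zip(again.records, sorted(comp1.records, key=lambda r: r.final_rank)):
            assert a.signed_fc == pytest.approx(b.signed_fc)
            assert a.method == b.method and a.final_rank == b.final_rank


# -- invariants ------------------------------------------------------------

# zeros exercise the floor; nonzero values stay well clear of the 0.01 floor
# so scaling cannot flip a floored comparison through float rounding
fpkm = st.one_of(
    st.just(0.0),
    st.floats(min_value=0.125, max_value=1000.0, allow_nan=False, width=32),
)
gene_values = st.tuples(
    st.lists(fpkm, min_size=2, max_size=4),
    st.lists(fpkm, min_size=2, max_size=4),
)


@given(gene_values, st.floats(min_value=0.01, max_value=100.0))
@settings(max_examples=200, deadline=None)
def test_scale_equivariance(vals, c):
    """Multiplying both sets (and the floor) by c preserves selection and
    signed_fc; the FPKM difference scales by c."""
    ref, test = vals
    base_delv = delv_test(ref, test, 0.01)
    scaled_delv = delv_test([v * c for v in ref], [v * c for v in test], 0.01 * c)
    assert scaled_delv.eligible == base_delv.eligible
    assert scaled_delv.selected == base_delv.selected
    if base_delv.eligible:
        assert scaled_delv.signed_fc == pytest.approx(base_delv.signed_fc, rel=1e-9)
        assert scaled_delv.fpkm_diff == pytest.approx(base_delv.fpkm_diff * c, rel=1e-9, abs=1e-9)
    base_srmm = srmm_test(ref, test, 0.01)
    scaled_srmm = srmm_test([v * c for v in ref], [v * c for v in test], 0.01 * c)
    assert scaled_srmm.selected == base_srmm.selected
    if base_srmm.separated:
        assert scaled_srmm.signed_fc == pytest.approx(base_srmm.signed_fc, rel=1e-9)


@given(gene_values)
@settings(max_examples=200, deadline=None)
def test_antisymmetry(vals):
    """Swapping reference and test negates signed_fc and fpkm_diff and
    preserves whether the gene is selected."""
    ref, test = vals
    fwd_d, rev_d = delv_test(ref, test, 0.01), delv_test(test, ref, 0.01)
    assert fwd_d.eligible == rev_d.eligible
    assert fwd_d.selected == rev_d.selected
    if fwd_d.eligible:
        if abs(fwd_d.signed_fc) != 1.0:  # |fc| = 1 is its own mirror image
            assert rev_d.signed_fc == pytest.approx(-fwd_d.signed_fc, rel=1e-9)
        assert rev_d.fpkm_diff == pytest.approx(-fwd_d.fpkm_diff, rel=1e-9, abs=1e-12)
    fwd_s, rev_s = srmm_test(ref, test, 0.01), srmm_test(test, ref, 0.01)
    assert fwd_s.separated == rev_s.separated
    assert fwd_s.selected == rev_s.selected
    if fwd_s.separated:
        assert rev_s.signed_fc == pytest.approx(-fwd_s.signed_fc, rel=1e-9)
        assert rev_s.fpkm_diff == pytest.approx(-fwd_s.fpkm_diff, rel=1e-9, abs=1e-12)


def test_every_emitted_record_has_twofold_change(comp1, comp2, comp7):
    for comp in (comp1, comp2, comp7):
        assert all(abs(r.signed_fc) >= 2.0 for r in comp.records)
        assert all(r.signed_fc * r.fpkm_diff > 0 for r in comp.records)
        assert sorted(r.final_rank for r in comp.records) == list(range(1, len(comp) + 1))
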