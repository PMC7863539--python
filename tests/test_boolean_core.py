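"""Sparse-quadrant statistics, implication classification, contrapositives."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boolimp import (
    Quadrant,
    QuadrantCounts,
    RelationKind,
    SignificanceParams,
    canonicalize_relation,
    classify_pair,
    quadrant_counts,
    sparsity_test,
)
from boolimp.boolean_core import passes_range_filter
from boolimp.stepminer import HIGH, INTERMEDIATE, LOW


# ---------------------------------------------------------------------------
# independent oracle: a literal, scalar transcription of the printed formulas,
# written without reference to the implementation


def oracle_test(a00, a01, a10, a11, cell, s_min=3.0, err_max=0.1):
    total = a00 + a01 + a10 + a11
    obs = {"q00": a00, "q01": a01, "q10": a10, "q11": a11}[cell]
    row = {"q00": a00 + a01, "q01": a00 + a01, "q10": a10 + a11, "q11": a10 + a11}[cell]
    col = {"q00": a00 + a10, "q01": a01 + a11, "q10": a00 + a10, "q11": a01 + a11}[cell]
    expected = (row / total) * (col / total) * total if total else 0.0
    if expected == 0:
        return False
    s = (expected - obs) / math.sqrt(expected)
    err = 0.5 * (obs / row + obs / col)
    return s > s_min and err < err_max


def oracle_classify(a00, a01, a10, a11, s_min=3.0, err_max=0.1):
    sparse = {c for c in ("q00", "q01", "q10", "q11")
              if oracle_test(a00, a01, a10, a11, c, s_min, err_max)}
    if sparse == {"q01", "q10"}:
        return "equivalent"
    if sparse == {"q00", "q11"}:
        return "opposite"
    if len(sparse) == 1:
        return {"q00": "low_high", "q01": "low_low",
                "q10": "high_high", "q11": "high_low"}[sparse.pop()]
    return "none"


# ---------------------------------------------------------------------------


class TestQuadrantCounts:
    def test_one_per_quadrant(self):
        da = np.array([LOW, LOW, HIGH, HIGH])
        db = np.array([LOW, HIGH, LOW, HIGH])
        q = quadrant_counts(da, db)
        assert (q.a00, q.a01, q.a10, q.a11) == (1, 1, 1, 1)
        assert q.n_used == 4 and q.n_dropped_intermediate == 0

    def test_intermediate_excluded(self):
        da = np.array([INTERMEDIATE, LOW, HIGH])
        db = np.array([LOW, LOW, HIGH])
        q = quadrant_counts(da, db)
        assert (q.a00, q.a01, q.a10, q.a11) == (1, 0, 0, 1)
        assert q.n_dropped_intermediate == 1

    def test_all_intermediate(self):
        q = quadrant_counts(np.full(5, INTERMEDIATE), np.full(5, INTERMEDIATE))
        assert q.n_used == 0 and q.n_dropped_intermediate == 5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            quadrant_counts(np.zeros(3), np.zeros(4))


class TestSparsityTest:
    def test_worked_arithmetic_q00(self):
        t = sparsity_test(QuadrantCounts(1, 50, 50, 50), Quadrant.Q00)
        assert t.expected == pytest.approx(51 * 51 / 151, abs=1e-9)
        assert t.s_statistic == pytest.approx((t.expected - 1) / math.sqrt(t.expected), abs=1e-9)
        assert t.error_rate == pytest.approx(0.5 * (1 / 51 + 1 / 51), abs=1e-9)
        assert t.passes

    def test_perfectly_sparse_quadrant(self):
        t = sparsity_test(QuadrantCounts(0, 10, 10, 10), Quadrant.Q00)
        assert t.observed == 0 and t.error_rate == 0.0
        assert t.s_statistic == pytest.approx(math.sqrt(100 / 30))

    def test_independent_table_s_zero(self):
        for q in Quadrant:
            t = sparsity_test(QuadrantCounts(25, 25, 25, 25), q)
            assert t.s_statistic == pytest.approx(0.0) and not t.passes

    def test_empty_marginal_undefined_not_error(self):
        t = sparsity_test(QuadrantCounts(0, 0, 5, 5), Quadrant.Q00)
        assert not t.defined and not t.passes

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            sparsity_test(QuadrantCounts(0, 0, 0, 0), Quadrant.Q00)

    def test_s_decreasing_in_observed(self):
        # marginals held roughly fixed; S must fall as the cell fills
        s_vals = [
            sparsity_test(QuadrantCounts(k, 50, 50, 50), Quadrant.Q00).s_statistic
            for k in range(0, 6)
        ]
        assert all(a > b for a, b in zip(s_vals, s_vals[1:]))


class TestClassifyPair:
    @pytest.mark.parametrize(
        "counts,kind",
        [
            ((50, 1, 1, 50), RelationKind.EQUIVALENT),
            ((1, 50, 50, 1), RelationKind.OPPOSITE),
            ((50, 50, 50, 1), RelationKind.HIGH_LOW),
            ((1, 50, 50, 50), RelationKind.LOW_HIGH),
            ((50, 1, 50, 50), RelationKind.LOW_LOW),
            ((50, 50, 1, 50), RelationKind.HIGH_HIGH),
            ((25, 25, 25, 25), RelationKind.NONE),
        ],
    )
    def test_prototype_tables(self, counts, kind):
        assert classify_pair(QuadrantCounts(*counts)).kind is kind

    def test_equivalent_supporting_tests(self):
        rel = classify_pair(QuadrantCounts(50, 1, 1, 50))
        t01, t10 = rel.test(Quadrant.Q01), rel.test(Quadrant.Q10)
        for t in (t01, t10):
            assert t.expected == pytest.approx(51 * 51 / 102)
            assert t.passes
        assert not rel.test(Quadrant.Q00).passes

    def test_exhaustive_small_tables_match_oracle(self):
        # all tables with cells in 0..4 (full 0..6 grid runs in acceptance)
        for a00, a01, a10, a11 in itertools.product(range(5), repeat=4):
            if a00 + a01 + a10 + a11 == 0:
                continue
            got = classify_pair(QuadrantCounts(a00, a01, a10, a11)).kind.value
            assert got == oracle_classify(a00, a01, a10, a11), (a00, a01, a10, a11)

    @settings(max_examples=300, deadline=None)
    @given(st.tuples(*[st.integers(0, 120)] * 4))
    def test_contrapositive_consistency(self, cells):
        """classify(A,B) and classify(B,A) canonicalize to the same record."""
        a00, a01, a10, a11 = cells
        if a00 + a01 + a10 + a11 == 0:
            return
        q_ab = QuadrantCounts(a00, a01, a10, a11)
        q_ba = QuadrantCounts(a00, a10, a01, a11)  # axes swapped
        r_ab = classify_pair(q_ab)
        r_ba = classify_pair(q_ba)
        if r_ab.kind is RelationKind.NONE:
            assert r_ba.kind is RelationKind.NONE
            return
        rec1 = canonicalize_relation("A", "B", r_ab)
        rec2 = canonicalize_relation("B", "A", r_ba)
        assert (rec1.otu_a, rec1.otu_b, rec1.kind) == (rec2.otu_a, rec2.otu_b, rec2.kind)

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(0, 120)] * 4))
    def test_equivalent_opposite_mutually_exclusive(self, cells):
        """A table where both microbes have both levels cannot be equivalent
        and opposite at once; classification returns a single kind."""
        if sum(cells) == 0:
            return
        kind = classify_pair(QuadrantCounts(*cells)).kind
        assert kind in RelationKind  # single, definite label


class TestCanonicalize:
    @pytest.mark.parametrize(
        "kind,swapped",
        [
            (RelationKind.LOW_LOW, RelationKind.HIGH_HIGH),
            (RelationKind.HIGH_HIGH, RelationKind.LOW_LOW),
            (RelationKind.LOW_HIGH, RelationKind.LOW_HIGH),
            (RelationKind.HIGH_LOW, RelationKind.HIGH_LOW),
            (RelationKind.EQUIVALENT, RelationKind.EQUIVALENT),
            (RelationKind.OPPOSITE, RelationKind.OPPOSITE),
        ],
    )
    def test_swap_kind_mapping(self, kind, swapped):
        rec = canonicalize_relation("B", "A", kind)
        assert (rec.otu_a, rec.otu_b, rec.kind) == ("A", "B", swapped)

    def test_already_ordered_unchanged(self):
        rec = canonicalize_relation("A", "B", RelationKind.LOW_LOW)
        assert (rec.otu_a, rec.otu_b, rec.kind) == ("A", "B", RelationKind.LOW_LOW)

    def test_none_rejected(self):
        with pytest.raises(ValueError):
            canonicalize_relation("A", "B", RelationKind.NONE)

    def test_counts_swapped_with_axes(self):
        q = QuadrantCounts(1, 2, 3, 4)
        rec = canonicalize_relation("B", "A", RelationKind.EQUIVALENT, q)
        assert (rec.counts.a00, rec.counts.a01, rec.counts.a10, rec.counts.a11) == (1, 3, 2, 4)


class TestRangeFilter:
    def test_balanced_passes(self):
        states = np.array([LOW] * 10 + [HIGH] * 10)
        assert passes_range_filter(states, SignificanceParams())

    def test_one_sided_fails(self):
        states = np.array([LOW] * 19 + [HIGH])
        assert not passes_range_filter(states, SignificanceParams())

    def test_disabled_filter_admits_everything(self):
        params = SignificanceParams(min_side_fraction=0.0, min_side_count=0)
        assert passes_range_filter(np.array([LOW] * 20), params)
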