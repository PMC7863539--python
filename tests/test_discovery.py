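"""All-pairs scanning, permutation FDR, invariants, correlation, metadata."""

import numpy as np
import pytest

from boolimp import (
    CountMatrix,
    PairSpec,
    RelationKind,
    SampleMetadata,
    correlate_by_relation,
    differential_metadata,
    find_invariants,
    generate_dataset,
    generate_multidataset,
    permutation_fdr,
    scan_pairs,
    threshold_matrix,
    transform_log2,
)
from boolimp.discovery import RelationTable


def _scan(am, **kw):
    _, dm = threshold_matrix(am)
    return scan_pairs(dm, **kw)


class TestScanPairs:
    def test_planted_pairs_recovered_exactly(self, planted_abundance):
        am, truth = planted_abundance
        rt = _scan(am)
        got = {(r.otu_a, r.otu_b): r.kind for r in rt.records}
        assert got == truth.planted_kinds()

    def test_pure_noise_yields_nothing(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 4096, size=(500, 20)).astype(float)
        cm = CountMatrix(counts, [f"s{i}" for i in range(500)], [f"m{i:02d}" for i in range(20)])
        rt = _scan(transform_log2(cm))
        assert rt.records == []

    def test_duplicated_column_is_equivalent(self, planted_abundance):
        am, _ = planted_abundance
        vals = np.column_stack([am.values, am.values[:, 0]])
        from boolimp.otu_io import AbundanceMatrix

        am2 = AbundanceMatrix(vals, am.sample_ids, am.otu_ids + ["ZZdup"])
        rt = _scan(am2)
        got = {(r.otu_a, r.otu_b): r.kind for r in rt.records}
        assert got[("OTU0000", "ZZdup")] is RelationKind.EQUIVALENT

    def test_invariant_to_column_and_row_order(self, planted_abundance):
        am, _ = planted_abundance
        rng = np.random.default_rng(3)
        cperm = rng.permutation(am.n_otus)
        rperm = rng.permutation(am.n_samples)
        from boolimp.otu_io import AbundanceMatrix

        am2 = AbundanceMatrix(
            am.values[np.ix_(rperm, cperm)],
            [am.sample_ids[i] for i in rperm],
            [am.otu_ids[j] for j in cperm],
        )
        r1 = [(r.otu_a, r.otu_b, r.kind) for r in _scan(am).records]
        r2 = [(r.otu_a, r.otu_b, r.kind) for r in _scan(am2).records]
        assert r1 == r2

    def test_pair_budget(self, planted_abundance):
        am, _ = planted_abundance
        rt = _scan(am)
        m = len(rt.testable_otus)
        assert rt.n_pairs_tested == m * (m - 1) // 2


class TestPermutationFdr:
    def test_planted_structure_low_fdr(self):
        cm, _ = generate_dataset(
            500, 30, [PairSpec(RelationKind.EQUIVALENT)] * 5 + [PairSpec(RelationKind.HIGH_LOW)] * 5,
            seed=11,
        )
        am = transform_log2(cm)
        res = permutation_fdr(am, n_perm=5, seed=1)
        assert res.n_original >= 10
        assert res.fdr is not None and res.fdr < 0.1

    def test_thresholds_invariant_under_permutation(self):
        cm, _ = generate_dataset(200, 10, [PairSpec(RelationKind.EQUIVALENT)], seed=5)
        am = transform_log2(cm)
        fits, _ = threshold_matrix(am)
        rng = np.random.default_rng(0)
        vals = np.column_stack([rng.permutation(am.values[:, j]) for j in range(am.n_otus)])
        from boolimp.otu_io import AbundanceMatrix

        fits2, _ = threshold_matrix(AbundanceMatrix(vals, am.sample_ids, am.otu_ids))
        for otu in am.otu_ids:
            assert fits2[otu].threshold == pytest.approx(fits[otu].threshold)

    def test_no_original_relations_fdr_undefined(self):
        rng = np.random.default_rng(13)
        counts = rng.integers(0, 4096, size=(300, 10)).astype(float)
        cm = CountMatrix(counts, [f"s{i}" for i in range(300)], [f"m{i}" for i in range(10)])
        res = permutation_fdr(transform_log2(cm), n_perm=3, seed=2)
        assert res.n_original == 0 and res.fdr is None

    def test_seed_reproducibility(self):
        cm, _ = generate_dataset(300, 12, [PairSpec(RelationKind.EQUIVALENT)], seed=9)
        am = transform_log2(cm)
        r1 = permutation_fdr(am, n_perm=3, seed=77)
        r2 = permutation_fdr(am, n_perm=3, seed=77)
        assert r1.per_permutation_counts == r2.per_permutation_counts

    def test_invalid_n_perm(self, planted_abundance):
        am, _ = planted_abundance
        with pytest.raises(ValueError):
            permutation_fdr(am, n_perm=0, seed=0)


def _table(dataset_id, kinds, testable):
    from boolimp.boolean_core import RelationRecord

    records = [RelationRecord(a, b, k) for (a, b), k in kinds.items()]
    return RelationTable(dataset_id, records, len(testable) * (len(testable) - 1) // 2,
                         sorted(testable))


class TestFindInvariants:
    def test_consistent_pair_nominated(self):
        tabs = [
            _table(f"d{i}", {("A", "B"): RelationKind.EQUIVALENT}, {"A", "B", "C"})
            for i in range(4)
        ]
        res = find_invariants(tabs)
        assert [(v.otu_a, v.otu_b, v.kind) for v in res.invariants] == [
            ("A", "B", RelationKind.EQUIVALENT)
        ]

    def test_contradicted_kind_excluded(self):
        tabs = [
            _table("d0", {("A", "B"): RelationKind.LOW_LOW}, {"A", "B"}),
            _table("d1", {("A", "B"): RelationKind.LOW_LOW}, {"A", "B"}),
            _table("d2", {("A", "B"): RelationKind.HIGH_HIGH}, {"A", "B"}),
        ]
        res = find_invariants(tabs)
        assert res.invariants == [] and res.n_inconsistent == 1

    def test_untestable_pair_tallied_separately(self):
        tabs = [
            _table("d0", {("A", "B"): RelationKind.LOW_LOW}, {"A", "B"}),
            _table("d1", {("A", "B"): RelationKind.LOW_LOW}, {"A", "B"}),
            _table("d2", {}, {"A"}),  # B untestable here
        ]
        res = find_invariants(tabs)
        assert res.invariants == []
        assert res.n_untestable == 1 and res.n_inconsistent == 0

    def test_order_independent(self):
        tabs = [
            _table("d0", {("A", "B"): RelationKind.OPPOSITE, ("A", "C"): RelationKind.LOW_LOW},
                   {"A", "B", "C"}),
            _table("d1", {("A", "B"): RelationKind.OPPOSITE}, {"A", "B", "C"}),
        ]
        fwd = find_invariants(tabs)
        rev = find_invariants(tabs[::-1])
        assert [(v.otu_a, v.otu_b, v.kind) for v in fwd.invariants] == [
            (v.otu_a, v.otu_b, v.kind) for v in rev.invariants
        ]

    def test_duplicate_dataset_id_rejected(self):
        t = _table("d0", {}, {"A", "B"})
        with pytest.raises(ValueError):
            find_invariants([t, t])

    def test_end_to_end_multidataset(self):
        sets = generate_multidataset(
            400, 12, [PairSpec(RelationKind.EQUIVALENT), PairSpec(RelationKind.LOW_LOW)],
            k=4, seed=21,
        )
        tabs = []
        for i, (cm, truth) in enumerate(sets):
            am = transform_log2(cm)
            _, dm = threshold_matrix(am)
            tabs.append(scan_pairs(dm, dataset_id=f"d{i}"))
        res = find_invariants(tabs)
        got = {(v.otu_a, v.otu_b): v.kind for v in res.invariants}
        for pair, kind in sets[0][1].planted_kinds().items():
            assert got.get(pair) == kind


class TestCorrelateByRelation:
    def test_equivalent_pairs_higher_r_than_asymmetric(self):
        cm, truth = generate_dataset(
            500, 20,
            [PairSpec(RelationKind.EQUIVALENT)] * 3 + [PairSpec(RelationKind.HIGH_LOW)] * 3,
            seed=31,
        )
        am = transform_log2(cm)
        rt = _scan(am)
        summary = correlate_by_relation(am, rt, subset_size=500, seed=0)
        assert summary.median_r(RelationKind.EQUIVALENT) > summary.median_r(RelationKind.HIGH_LOW)
        assert summary.per_pair["r"].between(-1, 1).all()

    def test_identical_columns_r_one(self, planted_abundance):
        am, _ = planted_abundance
        from boolimp.otu_io import AbundanceMatrix

        vals = np.column_stack([am.values, am.values[:, 0]])
        am2 = AbundanceMatrix(vals, am.sample_ids, am.otu_ids + ["ZZdup"])
        rt = _scan(am2)
        summary = correlate_by_relation(am2, rt, seed=0)
        row = summary.per_pair.set_index(["otu_a", "otu_b"]).loc[("OTU0000", "ZZdup")]
        assert row["r"] == pytest.approx(1.0)
        assert row["kind"] == "equivalent"

    def test_opposite_pair_negative_r(self):
        cm, _ = generate_dataset(400, 2, [PairSpec(RelationKind.OPPOSITE)], seed=41)
        am = transform_log2(cm)
        rt = _scan(am)
        summary = correlate_by_relation(am, rt, seed=0)
        assert (summary.per_pair["r"] < 0).all()


class TestDifferentialMetadata:
    def _setup(self, a_vals, b_vals):
        from boolimp.otu_io import AbundanceMatrix

        n = len(a_vals) + len(b_vals)
        sids = [f"s{i}" for i in range(n)]
        am = AbundanceMatrix(
            np.asarray(a_vals + b_vals, dtype=float).reshape(-1, 1), sids, ["otu1"]
        )
        meta = SampleMetadata(sids, {"grp": ["a"] * len(a_vals) + ["b"] * len(b_vals)})
        return am, meta

    def test_separated_groups(self):
        am, meta = self._setup([1.0, 1, 1, 1], [5.0, 5, 5, 5.001])
        df = differential_metadata(am, meta, "grp", "a", "b")
        row = df.iloc[0]
        assert row["mean_diff"] == pytest.approx(-4.0, abs=1e-3)
        assert row["p"] < 1e-6 and row["neg_log10_p"] > 6

    def test_identical_groups_null(self):
        am, meta = self._setup([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        df = differential_metadata(am, meta, "grp", "a", "b")
        assert df.iloc[0]["mean_diff"] == pytest.approx(0.0)
        assert df.iloc[0]["p"] == pytest.approx(1.0)

    def test_zero_variance_flagged_not_ranked(self):
        am, meta = self._setup([2.0, 2, 2], [2.0, 2, 2])
        df = differential_metadata(am, meta, "grp", "a", "b")
        assert np.isnan(df.iloc[-1]["p"])

    def test_small_group_errors(self):
        am, meta = self._setup([1.0], [2.0, 3, 4])
        with pytest.raises(ValueError):
            differential_metadata(am, meta, "grp", "a", "b")

    def test_welch_matches_scipy_oracle(self):
        from scipy import stats as ss

        rng = np.random.default_rng(5)
        a = rng.normal(3, 1, 10).tolist()
        b = rng.normal(5, 2, 14).tolist()
        am, meta = self._setup(a, b)
        df = differential_metadata(am, meta, "grp", "a", "b")
        ref = ss.ttest_ind(a, b, equal_var=False)
        assert df.iloc[0]["t"] == pytest.approx(ref.statistic)
        assert df.iloc[0]["p"] == pytest.approx(ref.pvalue)
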