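"""All-pairs implication scanning, permutation FDR, cross-dataset invariants,
correlation comparison and metadata differential analysis.

The scan visits every unordered pair of microbes that survive the dynamic
range filter, computes quadrant tables row-by-row (memory stays
O(samples x microbes), never O(pairs)) and keeps only pairs whose
classification is not ``none``.  Significance of the whole table is judged
by a permutation FDR: each microbe's values are shuffled independently
(which provably leaves every StepMiner threshold unchanged, so thresholds
are reused), relationships are recounted, and the FDR is the mean permuted
relationship count divided by the original count.

A relationship that is testable in every dataset of a collection and carries
the identical kind everywhere is nominated as a candidate universal
invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .boolean_core import (
    Quadrant,
    QuadrantCounts,
    Relation,
    RelationKind,
    RelationRecord,
    SignificanceParams,
    canonicalize_relation,
    classify_pair,
    passes_range_filter,
)
from .otu_io import AbundanceMatrix, SampleMetadata
from .stepminer import (
    HIGH,
    LOW,
    DiscreteMatrix,
    DiscretizationParams,
    threshold_matrix,
)

__all__ = [
    "RelationTable",
    "FdrResult",
    "InvariantRecord",
    "InvariantResult",
    "CorrSummary",
    "scan_pairs",
    "permutation_fdr",
    "find_invariants",
    "correlate_by_relation",
    "differential_metadata",
]


@dataclass
class RelationTable:
    """Output of one all-pairs scan.

    ``testable_otus`` is the set that survived the range filter; a pair is
    testable iff both members are in it, which downstream invariant logic
    needs to distinguish "no relationship" from "could not be tested".
    """

    dataset_id: str
    records: list[RelationRecord]
    n_pairs_tested: int
    testable_otus: list[str]
    sig_params: SignificanceParams = field(default_factory=SignificanceParams)
    disc_params: DiscretizationParams = field(default_factory=DiscretizationParams)

    def __post_init__(self) -> None:
        if self.n_pairs_tested < len(self.records):
            raise ValueError("more records than tested pairs")

    def kinds(self) -> dict[tuple[str, str], RelationKind]:
        return {(r.otu_a, r.otu_b): r.kind for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            c = r.counts
            row = {
                "otu_a": r.otu_a,
                "otu_b": r.otu_b,
                "kind": r.kind.value,
                "a00": c.a00 if c else None,
                "a01": c.a01 if c else None,
                "a10": c.a10 if c else None,
                "a11": c.a11 if c else None,
                "n_used": c.n_used if c else None,
            }
            for t in r.tests:
                row[f"S_{t.quadrant.value}"] = t.s_statistic
                row[f"err_{t.quadrant.value}"] = t.error_rate
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class FdrResult:
    """Permutation false-discovery estimate for one relation table."""

    n_original: int
    per_permutation_counts: list[int]
    n_perm: int
    seed: int

    @property
    def mean_permuted(self) -> float:
        return float(np.mean(self.per_permutation_counts)) if self.per_permutation_counts else 0.0

    @property
    def fdr(self) -> float | None:
        """mean permuted count / original count; None when nothing was found."""
        if self.n_original == 0:
            return None
        return self.mean_permuted / self.n_original


@dataclass(frozen=True)
class InvariantRecord:
    """A pair carrying the identical relationship in every dataset."""

    otu_a: str
    otu_b: str
    kind: RelationKind
    per_dataset: dict[str, RelationRecord] = field(default_factory=dict, hash=False)


@dataclass
class InvariantResult:
    invariants: list[InvariantRecord]
    n_untestable: int          # pairs significant somewhere but untestable elsewhere
    n_inconsistent: int        # testable everywhere but kinds disagree / missing
    dataset_ids: list[str]


@dataclass
class CorrSummary:
    """Pearson r per related pair plus a per-kind histogram over [-1, 1]."""

    per_pair: pd.DataFrame      # otu_a, otu_b, kind, r
    histogram: pd.DataFrame     # bin_left, bin_right, one count column per kind
    n_excluded_zero_variance: int
    subset_otus: list[str]

    def median_r(self, kind: RelationKind | str) -> float:
        kind = RelationKind(kind).value
        sel = self.per_pair[self.per_pair["kind"] == kind]["r"]
        return float(sel.median()) if len(sel) else math.nan


# ---------------------------------------------------------------------------
# all-pairs scan


def _indicators(dm: DiscreteMatrix) -> tuple[np.ndarray, np.ndarray]:
    low = (dm.states == LOW).astype(np.float64)
    high = (dm.states == HIGH).astype(np.float64)
    return low, high


def scan_pairs(
    dm: DiscreteMatrix,
    params: SignificanceParams = SignificanceParams(),
    dataset_id: str = "dataset",
    disc_params: DiscretizationParams = DiscretizationParams(),
) -> RelationTable:
    """Classify every unordered pair of range-filtered microbes.

    Records are canonicalized (smaller OTU id first) and contain only pairs
    with a definite implication kind.  Deterministic: independent of microbe
    column order and sample row order.
    """
    testable_idx = [
        j for j in range(dm.n_otus) if passes_range_filter(dm.states[:, j], params)
    ]
    testable = [dm.otu_ids[j] for j in testable_idx]
    # scan in sorted-id order so output is independent of column order
    order = sorted(range(len(testable)), key=lambda k: testable[k])
    idx = [testable_idx[k] for k in order]
    ids = [testable[k] for k in order]

    records: list[RelationRecord] = []
    n_pairs = 0
    if len(idx) >= 2:
        low, high = _indicators(dm)
        L = low[:, idx]
        H = high[:, idx]
        m = len(idx)
        for i in range(m - 1):
            li, hi = L[:, i], H[:, i]
            rest = slice(i + 1, m)
            a00 = li @ L[:, rest]
            a01 = li @ H[:, rest]
            a10 = hi @ L[:, rest]
            a11 = hi @ H[:, rest]
            n_pairs += m - 1 - i
            # vectorized screen: does any quadrant pass S/err for this row?
            cand = _screen(a00, a01, a10, a11, params)
            for off in np.nonzero(cand)[0]:
                j = i + 1 + off
                counts = QuadrantCounts(
                    int(a00[off]), int(a01[off]), int(a10[off]), int(a11[off]),
                    n_dropped_intermediate=dm.n_samples - int(
                        a00[off] + a01[off] + a10[off] + a11[off]
                    ),
                )
                rel = classify_pair(counts, params)
                if rel.kind is not RelationKind.NONE:
                    records.append(canonicalize_relation(ids[i], ids[j], rel, counts))
    records.sort(key=lambda r: (r.otu_a, r.otu_b))
    return RelationTable(dataset_id, records, n_pairs, sorted(testable), params, disc_params)


def _screen(a00, a01, a10, a11, params: SignificanceParams) -> np.ndarray:
    """Vectorized any-quadrant-passes mask over one row of pair tables."""
    total = a00 + a01 + a10 + a11
    any_pass = np.zeros(a00.shape, dtype=bool)
    margins = {
        "q00": (a00, a00 + a01, a00 + a10),
        "q01": (a01, a00 + a01, a01 + a11),
        "q10": (a10, a10 + a11, a00 + a10),
        "q11": (a11, a10 + a11, a01 + a11),
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        for obs, row, col in margins.values():
            expected = np.where(total > 0, row * col / np.maximum(total, 1), 0.0)
            ok = expected > 0
            s = np.where(ok, (expected - obs) / np.sqrt(np.maximum(expected, 1e-300)), -np.inf)
            err = np.where(ok, 0.5 * (obs / np.maximum(row, 1) + obs / np.maximum(col, 1)), np.inf)
            any_pass |= ok & (s > params.s_min) & (err < params.err_max)
    return any_pass


# ---------------------------------------------------------------------------
# permutation FDR


def permutation_fdr(
    am: AbundanceMatrix,
    sig_params: SignificanceParams = SignificanceParams(),
    disc_params: DiscretizationParams = DiscretizationParams(),
    n_perm: int = 10,
    seed: int = 0,
    original: RelationTable | None = None,
) -> FdrResult:
    """Estimate the FDR by independently permuting each microbe's values.

    Per round, every microbe's samples are shuffled independently and the
    all-pairs scan is repeated with identical parameters.  Step thresholds
    are permutation-invariant, so the discretized states are shuffled
    directly instead of refitting.  A single integer seed drives all rounds;
    shuffles are drawn in fixed microbe order for reproducibility.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fits, dm = threshold_matrix(am, disc_params)
    if original is None:
        original = scan_pairs(dm, sig_params, am_id(am), disc_params)
    rng = np.random.default_rng(seed)
    counts: list[int] = []
    for _ in range(n_perm):
        perm_states = np.empty_like(dm.states)
        for j in range(dm.n_otus):
            perm_states[:, j] = rng.permutation(dm.states[:, j])
        pdm = DiscreteMatrix(perm_states, dm.sample_ids, dm.otu_ids, dm.degenerate_otus)
        counts.append(len(scan_pairs(pdm, sig_params, "perm", disc_params).records))
    return FdrResult(len(original.records), counts, n_perm, seed)


def am_id(am: AbundanceMatrix) -> str:
    return "dataset"


# ---------------------------------------------------------------------------
# cross-dataset invariants


def find_invariants(tables: list[RelationTable]) -> InvariantResult:
    """Nominate pairs whose identical relationship recurs in every dataset.

    A pair must have been testable (both microbes passed the range filter)
    in every table and must appear with the same kind in each; pairs
    significant somewhere but untestable elsewhere are tallied separately
    rather than counted as inconsistent.  Order-independent in the table
    list.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 relation tables")
    ids = [t.dataset_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate dataset_id in {ids}")
    testable_sets = [set(t.testable_otus) for t in tables]
    kind_maps = [t.kinds() for t in tables]
    candidate_pairs = sorted(set().union(*[set(k) for k in kind_maps]))

    invariants: list[InvariantRecord] = []
    n_untestable = 0
    n_inconsistent = 0
    rec_maps = [{(r.otu_a, r.otu_b): r for r in t.records} for t in tables]
    for pair in candidate_pairs:
        a, b = pair
        if not all(a in ts and b in ts for ts in testable_sets):
            n_untestable += 1
            continue
        kinds = [km.get(pair) for km in kind_maps]
        if kinds[0] is not None and all(k == kinds[0] for k in kinds):
            invariants.append(
                InvariantRecord(
                    a, b, kinds[0],
                    {t.dataset_id: rm[pair] for t, rm in zip(tables, rec_maps)},
                )
            )
        else:
            n_inconsistent += 1
    return InvariantResult(invariants, n_untestable, n_inconsistent, ids)


# ---------------------------------------------------------------------------
# correlation comparison


def correlate_by_relation(
    am: AbundanceMatrix,
    rt: RelationTable,
    subset_size: int = 500,
    seed: int = 0,
    n_bins: int = 20,
) -> CorrSummary:
    """Pearson r (on log2 values, all samples) for related pairs of a subset.

    Mirrors the published comparison: at most ``subset_size`` microbes are
    sampled, every relation-table pair within the subset gets a Pearson
    coefficient, and the distribution is histogrammed per implication kind.
    Intermediate samples are deliberately retained — correlation sees the
    same points the scatter plot shows.
    """
    rng = np.random.default_rng(seed)
    if am.n_otus > subset_size:
        subset = sorted(rng.choice(am.otu_ids, size=subset_size, replace=False).tolist())
    else:
        subset = sorted(am.otu_ids)
    subset_set = set(subset)
    col = {o: am.values[:, am.otu_ids.index(o)] for o in subset}
    rows = []
    n_excluded = 0
    for r in rt.records:
        if r.otu_a not in subset_set or r.otu_b not in subset_set:
            continue
        x, y = col[r.otu_a], col[r.otu_b]
        if np.std(x) == 0 or np.std(y) == 0:
            n_excluded += 1
            continue
        rows.append(
            {"otu_a": r.otu_a, "otu_b": r.otu_b, "kind": r.kind.value,
             "r": float(stats.pearsonr(x, y).statistic)}
        )
    per_pair = pd.DataFrame(rows, columns=["otu_a", "otu_b", "kind", "r"])
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    hist = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    for kind in RelationKind:
        if kind is RelationKind.NONE:
            continue
        vals = per_pair[per_pair["kind"] == kind.value]["r"].to_numpy()
        hist[kind.value] = np.histogram(vals, bins=edges)[0]
    return CorrSummary(per_pair, pd.DataFrame(hist), n_excluded, subset)


# ---------------------------------------------------------------------------
# metadata differential


def differential_metadata(
    am: AbundanceMatrix,
    meta: SampleMetadata,
    factor: str,
    group_a: str,
    group_b: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-OTU two-group differential on log2 values.

    Welch's t-test by default (``equal_var=True`` for Student's).  Returns a
    frame with ``mean_diff`` (group_a - group_b), ``t``, ``p`` and
    ``neg_log10_p``, ranked by descending -log10(p) with ties broken by
    |mean difference|.  OTUs with an undefined statistic (zero variance in
    both groups) are kept at the bottom with NaN p.
    """
    fmap = meta.factor(factor)
    in_a = [i for i, s in enumerate(am.sample_ids) if fmap.get(s) == group_a]
    in_b = [i for i, s in enumerate(am.sample_ids) if fmap.get(s) == group_b]
    if not in_a or not in_b:
        raise ValueError(f"empty group(s) for factor {factor!r}: {group_a!r} or {group_b!r}")
    if len(in_a) < 2 or len(in_b) < 2:
        raise ValueError("each group needs >= 2 samples for a defined p value")
    xa = am.values[in_a, :]
    xb = am.values[in_b, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(xa, xb, axis=0, equal_var=equal_var)
    mean_diff = xa.mean(axis=0) - xb.mean(axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    t = np.asarray(res.statistic, dtype=float)
    with np.errstate(divide="ignore"):
        nlp = -np.log10(p)
    df = pd.DataFrame(
        {
            "otu_id": am.otu_ids,
            "mean_diff": mean_diff,
            "t": t,
            "p": p,
            "neg_log10_p": nlp,
            "n_a": len(in_a),
            "n_b": len(in_b),
        }
    )
    defined = df["p"].notna()
    df = pd.concat(
        [
            df[defined].sort_values(
                ["neg_log10_p", "mean_diff"],
                key=lambda s: s.abs() if s.name == "mean_diff" else s,
                ascending=False,
            ),
            df[~defined],
        ]
    ).reset_index(drop=True)
    return df
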