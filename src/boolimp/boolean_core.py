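"""BooleanNet sparse-quadrant statistics and implication classification.

A pair of discretized microbes (A on the x-axis, B on the y-axis) defines a
2x2 contingency table over the samples in which both are called low or high
(intermediates are dropped).  A Boolean implication holds when one quadrant
is significantly sparser than an independence model predicts:

    expected = row_marginal * col_marginal / total        (for that cell)
    S        = (expected - observed) / sqrt(expected)
    error    = 1/2 * (observed/row_marginal + observed/col_marginal)

and the test passes when S > s_min (default 3) and error < err_max
(default 0.1).  One sparse quadrant gives an asymmetric implication; both
off-diagonal quadrants sparse means the microbes are equivalent; both
diagonal quadrants sparse means they are opposite.

The quadrant-to-implication mapping: a sparse (A low, B low) quadrant means
A is almost never low while B is low, i.e. "A low implies B high"; the other
three follow by symmetry.

Asymmetric implications come in contrapositive pairs ("A high -> B low" is
the same statement as "B high -> A low"); :func:`canonicalize_relation`
rewrites every record with the lexicographically smaller OTU id first so
each unordered pair appears exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .stepminer import HIGH, INTERMEDIATE, LOW

__all__ = [
    "Quadrant",
    "RelationKind",
    "QuadrantCounts",
    "SparsityTest",
    "SignificanceParams",
    "Relation",
    "RelationRecord",
    "quadrant_counts",
    "sparsity_test",
    "classify_pair",
    "canonicalize_relation",
    "passes_range_filter",
]


class Quadrant(str, Enum):
    """Cells of the (A, B) table: q<A><B> with 0 = low, 1 = high."""

    Q00 = "q00"
    Q01 = "q01"
    Q10 = "q10"
    Q11 = "q11"


class RelationKind(str, Enum):
    NONE = "none"
    LOW_LOW = "low_low"      # A low  -> B low
    LOW_HIGH = "low_high"    # A low  -> B high
    HIGH_LOW = "high_low"    # A high -> B low
    HIGH_HIGH = "high_high"  # A high -> B high
    EQUIVALENT = "equivalent"
    OPPOSITE = "opposite"


#: Sparse quadrant -> implied asymmetric relationship.
#: An empty (A low, B low) corner forces "A low -> B high", etc.
_QUADRANT_TO_KIND = {
    Quadrant.Q00: RelationKind.LOW_HIGH,
    Quadrant.Q01: RelationKind.LOW_LOW,
    Quadrant.Q10: RelationKind.HIGH_HIGH,
    Quadrant.Q11: RelationKind.HIGH_LOW,
}

#: Kind substitution when the pair is reported with the axes swapped
#: (contrapositive): A low -> B low becomes B high -> A high, etc.
_SWAP_KIND = {
    RelationKind.LOW_LOW: RelationKind.HIGH_HIGH,
    RelationKind.HIGH_HIGH: RelationKind.LOW_LOW,
    RelationKind.LOW_HIGH: RelationKind.LOW_HIGH,
    RelationKind.HIGH_LOW: RelationKind.HIGH_LOW,
    RelationKind.EQUIVALENT: RelationKind.EQUIVALENT,
    RelationKind.OPPOSITE: RelationKind.OPPOSITE,
}


@dataclass(frozen=True)
class QuadrantCounts:
    """2x2 table of a pair: a<A><B> with 0 = low, 1 = high."""

    a00: int
    a01: int
    a10: int
    a11: int
    n_dropped_intermediate: int = 0

    def __post_init__(self) -> None:
        for c in (self.a00, self.a01, self.a10, self.a11, self.n_dropped_intermediate):
            if c < 0:
                raise ValueError("quadrant counts must be non-negative")

    @property
    def n_used(self) -> int:
        return self.a00 + self.a01 + self.a10 + self.a11

    def cell(self, q: Quadrant) -> int:
        return {"q00": self.a00, "q01": self.a01, "q10": self.a10, "q11": self.a11}[q.value]

    def marginals(self, q: Quadrant) -> tuple[int, int]:
        """(row, col) marginals of a cell: A-side total, B-side total."""
        a_low = self.a00 + self.a01
        a_high = self.a10 + self.a11
        b_low = self.a00 + self.a10
        b_high = self.a01 + self.a11
        row = a_low if q in (Quadrant.Q00, Quadrant.Q01) else a_high
        col = b_low if q in (Quadrant.Q00, Quadrant.Q10) else b_high
        return row, col

    def swapped(self) -> "QuadrantCounts":
        """The same samples tabulated with B on the x-axis."""
        return QuadrantCounts(self.a00, self.a10, self.a01, self.a11, self.n_dropped_intermediate)


@dataclass(frozen=True)
class SignificanceParams:
    """Thresholds of the sparse-quadrant test plus the dynamic-range filter.

    ``s_min`` and ``err_max`` are the published significance cut-offs.  The
    range filter (``min_side_fraction``, ``min_side_count``) demands that a
    microbe have enough samples on both sides of its threshold before it
    enters pair testing; near-constant microbes otherwise produce vacuous
    implications.  Set both to 0 to disable.
    """

    s_min: float = 3.0
    err_max: float = 0.1
    min_side_fraction: float = 0.05
    min_side_count: int = 3

    def __post_init__(self) -> None:
        if self.s_min <= 0:
            raise ValueError("s_min must be > 0")
        if not 0 < self.err_max < 1:
            raise ValueError("err_max must be in (0, 1)")

    def min_side(self, n_samples: int) -> int:
        return max(self.min_side_count, math.ceil(self.min_side_fraction * n_samples))


@dataclass(frozen=True)
class SparsityTest:
    """Result of testing one quadrant for sparsity against independence."""

    quadrant: Quadrant
    expected: float
    observed: int
    s_statistic: float
    error_rate: float
    passes: bool
    defined: bool = True


@dataclass(frozen=True)
class Relation:
    """Classification of one (A, B) pair; A is the x-axis microbe."""

    kind: RelationKind
    tests: tuple[SparsityTest, ...] = ()

    def test(self, q: Quadrant) -> SparsityTest:
        for t in self.tests:
            if t.quadrant == q:
                return t
        raise KeyError(q)


@dataclass(frozen=True)
class RelationRecord:
    """A canonicalized pair relationship (otu_a <= otu_b lexicographically)."""

    otu_a: str
    otu_b: str
    kind: RelationKind
    counts: QuadrantCounts | None = None
    tests: tuple[SparsityTest, ...] = ()


def quadrant_counts(da: np.ndarray, db: np.ndarray) -> QuadrantCounts:
    """Tabulate two discrete vectors, dropping samples intermediate in either."""
    da = np.asarray(da)
    db = np.asarray(db)
    if da.shape != db.shape:
        raise ValueError(f"length mismatch: {da.shape} vs {db.shape}")
    used = (da != INTERMEDIATE) & (db != INTERMEDIATE)
    a, b = da[used], db[used]
    return QuadrantCounts(
        a00=int(np.sum((a == LOW) & (b == LOW))),
        a01=int(np.sum((a == LOW) & (b == HIGH))),
        a10=int(np.sum((a == HIGH) & (b == LOW))),
        a11=int(np.sum((a == HIGH) & (b == HIGH))),
        n_dropped_intermediate=int(da.size - used.sum()),
    )


def sparsity_test(
    q: QuadrantCounts, quadrant: Quadrant, params: SignificanceParams = SignificanceParams()
) -> SparsityTest:
    """Test one quadrant for significant sparsity under independence.

    A zero expected count (empty marginal) leaves S and the error rate
    undefined; the test is then reported as not passing rather than raising,
    so an all-pairs scan never aborts on a degenerate table.
    """
    total = q.n_used
    if total == 0:
        raise ValueError("empty table: all samples intermediate")
    row, col = q.marginals(quadrant)
    observed = q.cell(quadrant)
    expected = row * col / total
    if expected == 0:
        return SparsityTest(quadrant, 0.0, observed, math.nan, math.nan, False, defined=False)
    s = (expected - observed) / math.sqrt(expected)
    error = 0.5 * (observed / row + observed / col)
    passes = (s > params.s_min) and (error < params.err_max)
    return SparsityTest(quadrant, expected, observed, s, error, passes)


def classify_pair(
    q: QuadrantCounts, params: SignificanceParams = SignificanceParams()
) -> Relation:
    """Classify a pair's table into one of the six implication kinds or none.

    All four quadrants are tested; exactly one sparse quadrant yields the
    corresponding asymmetric implication, both off-diagonal quadrants yield
    equivalent, both diagonal quadrants yield opposite, and anything else —
    no sparse quadrant, or a combination such as three sparse quadrants that
    violates the implication model — is none.  The per-quadrant tests are
    retained on the result for audit either way.
    """
    tests = tuple(sparsity_test(q, quad, params) for quad in Quadrant)
    passing = frozenset(t.quadrant for t in tests if t.passes)
    if passing == {Quadrant.Q01, Quadrant.Q10}:
        kind = RelationKind.EQUIVALENT
    elif passing == {Quadrant.Q00, Quadrant.Q11}:
        kind = RelationKind.OPPOSITE
    elif len(passing) == 1:
        kind = _QUADRANT_TO_KIND[next(iter(passing))]
    else:
        kind = RelationKind.NONE
    return Relation(kind, tests)


def canonicalize_relation(otu_a: str, otu_b: str, r: Relation | RelationKind,
                          counts: QuadrantCounts | None = None) -> RelationRecord:
    """Rewrite a relation so the lexicographically smaller OTU id comes first.

    Swapping the axes replaces each asymmetric kind by its contrapositive
    (low_low <-> high_high; low_high and high_low are self-dual) and leaves
    symmetric kinds untouched.
    """
    if isinstance(r, Relation):
        kind, tests = r.kind, r.tests
    else:
        kind, tests = r, ()
    if kind is RelationKind.NONE:
        raise ValueError("cannot canonicalize a 'none' relation")
    if otu_a <= otu_b:
        return RelationRecord(otu_a, otu_b, kind, counts, tests)
    return RelationRecord(
        otu_b, otu_a, _SWAP_KIND[kind],
        counts.swapped() if counts is not None else None,
        tests,
    )


def passes_range_filter(states: np.ndarray, params: SignificanceParams) -> bool:
    """True when a microbe has enough low AND high calls to be testable."""
    need = params.min_side(states.size)
    n_low = int(np.sum(states == LOW))
    n_high = int(np.sum(states == HIGH))
    return n_low >= need and n_high >= need
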