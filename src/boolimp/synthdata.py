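"""Synthetic OTU count matrices with planted Boolean implication structure.

Real microbiome log2 abundances are frequently bimodal per microbe — a low
mode (absent / rare) and a high mode (established) — and an implication
between two microbes shows up as one empty or nearly-empty quadrant of
their joint scatter.  The generator builds pairs directly in that quadrant
geometry: each sample is assigned a quadrant with specified probabilities,
the sparse quadrant(s) of the planted kind receive only a small "leak"
mass, and values are drawn normally around the low/high modes.  Log2 values
are then back-transformed to integer counts so fixtures exercise the same
I/O and log-transform path as real tables.

What this deliberately does not emulate: 16S compositionality (closure),
taxon-taxon correlations beyond the planted pairs, and sequencing-depth
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boolean_core import RelationKind
from .otu_io import CountMatrix

__all__ = [
    "PairSpec",
    "SyntheticTruth",
    "plant_pair",
    "generate_dataset",
    "generate_multidataset",
]

#: Quadrant order used throughout: (A,B) = (low,low), (low,high), (high,low), (high,high)
_QUADS = ("q00", "q01", "q10", "q11")

#: Which quadrants are sparse for each planted kind.
SPARSE_QUADRANTS: dict[RelationKind, tuple[str, ...]] = {
    RelationKind.LOW_HIGH: ("q00",),
    RelationKind.LOW_LOW: ("q01",),
    RelationKind.HIGH_HIGH: ("q10",),
    RelationKind.HIGH_LOW: ("q11",),
    RelationKind.EQUIVALENT: ("q01", "q10"),
    RelationKind.OPPOSITE: ("q00", "q11"),
    RelationKind.NONE: (),
}


@dataclass(frozen=True)
class PairSpec:
    """Recipe for one planted pair.

    ``leak_rate`` is the total probability mass placed in the sparse
    quadrant(s); the remainder is spread over the non-sparse quadrants by
    ``quadrant_weights`` (uniform when omitted).  ``low_mode``/``high_mode``
    are log2 abundance centers and ``noise_sd`` the normal spread around
    them; a "strong" spec keeps ``high_mode - low_mode > 2*(noise_sd+0.5)``
    so the noise margin cannot swallow a mode.  Defaults (4 and 8 log2
    units, sd 0.5, leak 0.02) give the 4-unit separation regime the
    detector is calibrated for while still exercising the error-rate test.
    """

    kind: RelationKind
    low_mode: float = 4.0
    high_mode: float = 8.0
    noise_sd: float = 0.5
    leak_rate: float = 0.02
    quadrant_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.leak_rate < 1:
            raise ValueError("leak_rate must be in [0, 1)")
        if self.high_mode <= self.low_mode:
            raise ValueError("high_mode must exceed low_mode")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.quadrant_weights is not None:
            w = np.asarray(self.quadrant_weights, dtype=float)
            if w.size != len(self.dense_quadrants) or np.any(w < 0) or w.sum() == 0:
                raise ValueError(
                    f"need {len(self.dense_quadrants)} non-negative weights summing > 0"
                )

    @property
    def sparse_quadrants(self) -> tuple[str, ...]:
        return SPARSE_QUADRANTS[RelationKind(self.kind)]

    @property
    def dense_quadrants(self) -> tuple[str, ...]:
        return tuple(q for q in _QUADS if q not in self.sparse_quadrants)

    def quadrant_probs(self) -> np.ndarray:
        """Probability over (q00, q01, q10, q11)."""
        p = np.zeros(4)
        sparse = self.sparse_quadrants
        dense = self.dense_quadrants
        if self.quadrant_weights is None:
            w = np.full(len(dense), 1.0 / len(dense))
        else:
            w = np.asarray(self.quadrant_weights, dtype=float)
            w = w / w.sum()
        for q, wi in zip(dense, w):
            p[_QUADS.index(q)] = wi * (1.0 - (self.leak_rate if sparse else 0.0))
        if sparse:
            for q in sparse:
                p[_QUADS.index(q)] = self.leak_rate / len(sparse)
        return p


@dataclass
class SyntheticTruth:
    """Ground truth of a generated matrix: planted pairs, decoys, seed."""

    planted: list[tuple[str, str, PairSpec]]
    decoy_otus: list[str]
    seed: int | None
    n_samples: int

    def planted_kinds(self) -> dict[tuple[str, str], RelationKind]:
        out = {}
        for a, b, spec in self.planted:
            lo, hi = (a, b) if a <= b else (b, a)
            kind = RelationKind(spec.kind)
            if a > b:
                from .boolean_core import _SWAP_KIND

                kind = _SWAP_KIND[kind]
            out[(lo, hi)] = kind
        return out


def plant_pair(
    spec: PairSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw log2 abundances (valuesA, valuesB) for one planted pair.

    Each sample picks a quadrant from the spec's probabilities; A takes the
    low or high mode according to the quadrant's first index, B according to
    the second, plus normal noise.  With ``leak_rate`` 0 the sparse
    quadrant(s) receive exactly zero samples.
    """
    if n < 8:
        raise ValueError("need n >= 8 samples")
    probs = spec.quadrant_probs()
    quad = rng.choice(4, size=n, p=probs)
    a_high = quad >= 2          # q10, q11
    b_high = (quad % 2) == 1    # q01, q11
    va = np.where(a_high, spec.high_mode, spec.low_mode) + rng.normal(0, spec.noise_sd, n)
    vb = np.where(b_high, spec.high_mode, spec.low_mode) + rng.normal(0, spec.noise_sd, n)
    return va, vb


def _decoy_column(
    n: int, rng: np.random.Generator, mode: str, planted_pool: list[np.ndarray],
    low_mode: float, high_mode: float, noise_sd: float,
) -> np.ndarray:
    if mode == "unimodal":
        center = rng.uniform(low_mode, high_mode)
        return rng.normal(center, max(noise_sd, 0.5), n)
    if mode == "bimodal":
        frac = rng.uniform(0.3, 0.7)
        hi = rng.random(n) < frac
        return np.where(hi, high_mode, low_mode) + rng.normal(0, noise_sd, n)
    if mode == "shuffled":
        if planted_pool:
            src = planted_pool[rng.integers(len(planted_pool))]
            return rng.permutation(src)
        return _decoy_column(n, rng, "bimodal", planted_pool, low_mode, high_mode, noise_sd)
    raise ValueError(f"unknown decoy mode {mode!r}")


def generate_dataset(
    n_samples: int,
    n_microbes: int,
    planted: list[PairSpec],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    decoy_mode: str = "mixed",
    pseudocount: float = 1.0,
    otu_prefix: str = "OTU",
    sample_prefix: str = "S",
) -> tuple[CountMatrix, SyntheticTruth]:
    """Emit an integer count matrix with planted pairs and independent decoys.

    Planted pair i occupies microbes 2i and 2i+1; remaining columns are
    decoys ("unimodal", "bimodal", "shuffled" copies of planted columns, or
    the default "mixed" which alternates unimodal and shuffled).  Log2
    values v become counts ``max(round(2^v - pseudocount), 0)`` so that the
    standard log2(count + pseudocount) transform recovers them up to
    rounding.
    """
    if 2 * len(planted) > n_microbes:
        raise ValueError("planted pairs do not fit within n_microbes")
    if rng is None:
        rng = np.random.default_rng(seed)
    otu_ids = [f"{otu_prefix}{k:04d}" for k in range(n_microbes)]
    sample_ids = [f"{sample_prefix}{k:04d}" for k in range(n_samples)]
    log2vals = np.empty((n_samples, n_microbes))
    truth_pairs: list[tuple[str, str, PairSpec]] = []
    planted_cols: list[np.ndarray] = []
    for i, spec in enumerate(planted):
        va, vb = plant_pair(spec, n_samples, rng)
        log2vals[:, 2 * i] = va
        log2vals[:, 2 * i + 1] = vb
        truth_pairs.append((otu_ids[2 * i], otu_ids[2 * i + 1], spec))
        planted_cols.extend([va, vb])
    lo = min((s.low_mode for s in planted), default=4.0)
    hi = max((s.high_mode for s in planted), default=8.0)
    sd = max((s.noise_sd for s in planted), default=0.5)
    decoys = []
    for k, j in enumerate(range(2 * len(planted), n_microbes)):
        mode = ("unimodal", "shuffled")[k % 2] if decoy_mode == "mixed" else decoy_mode
        log2vals[:, j] = _decoy_column(n_samples, rng, mode, planted_cols, lo, hi, sd)
        decoys.append(otu_ids[j])
    counts = np.maximum(np.round(np.exp2(log2vals) - pseudocount), 0.0)
    cm = CountMatrix(counts, sample_ids, otu_ids)
    return cm, SyntheticTruth(truth_pairs, decoys, seed, n_samples)


def generate_multidataset(
    n_samples: int,
    n_microbes: int,
    planted: list[PairSpec],
    k: int,
    seed: int | None = None,
    size_jitter: float = 0.25,
    noise_jitter: float = 0.2,
    decoy_mode: str = "mixed",
) -> list[tuple[CountMatrix, SyntheticTruth]]:
    """k independent datasets sharing one planted truth.

    Each dataset redraws all noise, jitters the sample count by up to
    ``size_jitter`` (fractional) and the noise sd by up to ``noise_jitter``,
    emulating independent cohorts that obey the same underlying rules.
    """
    if k < 2:
        raise ValueError("need k >= 2 datasets")
    rng = np.random.default_rng(seed)
    out = []
    for d in range(k):
        n_d = max(8, int(round(n_samples * (1 + rng.uniform(-size_jitter, size_jitter)))))
        specs = [
            PairSpec(
                kind=s.kind,
                low_mode=s.low_mode,
                high_mode=s.high_mode,
                noise_sd=s.noise_sd * (1 + rng.uniform(-noise_jitter, noise_jitter)),
                leak_rate=s.leak_rate,
                quadrant_weights=s.quadrant_weights,
            )
            for s in planted
        ]
        out.append(
            generate_dataset(
                n_d, n_microbes, specs, rng=rng, decoy_mode=decoy_mode,
                sample_prefix=f"D{d}S",
            )
        )
    return out
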