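"""StepMiner: one-step function fitting and low/intermediate/high calls.

Each microbe's log2 abundances are sorted and a single step-up function is
fitted by exhaustive search over split positions, minimizing the sum of
squared errors around the two side means.  The threshold t is the midpoint
(m1 + m2) / 2 of the fitted levels; samples within a noise margin (default
0.5 log2 units) of t are called intermediate and ignored by the Boolean
statistics.  Because the fit operates on sorted values only a step-up is
possible, and the result is invariant to any permutation of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StepFit",
    "DiscretizationParams",
    "LOW",
    "INTERMEDIATE",
    "HIGH",
    "DiscreteMatrix",
    "InsufficientDataError",
    "fit_step",
    "discretize",
    "threshold_matrix",
]

LOW, INTERMEDIATE, HIGH = 0, 1, 2

MIN_SAMPLES = 4  # one value per side plus room for a step


class InsufficientDataError(ValueError):
    """Fewer than the minimum number of values for a step fit."""


@dataclass(frozen=True)
class StepFit:
    """A fitted one-step function.

    Attributes
    ----------
    threshold
        ``(left_mean + right_mean) / 2`` — where the step crosses between
        its two levels.
    step_index
        Number of samples on the low side of the step (1..n-1).
    left_mean, right_mean
        Means of the sorted values below / at-or-above the step.
    sse
        Sum of squared errors of the fitted step.
    degenerate
        True when the input has zero range; the threshold is then the common
        value and discretization is meaningless.
    """

    threshold: float
    step_index: int
    left_mean: float
    right_mean: float
    sse: float
    degenerate: bool = False


@dataclass(frozen=True)
class DiscretizationParams:
    """Noise half-width around the threshold; values within it are intermediate."""

    margin: float = 0.5

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


@dataclass
class DiscreteMatrix:
    """Per-sample low/intermediate/high calls, samples x OTUs (uint8 codes)."""

    states: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    degenerate_otus: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError("state matrix shape does not match id lists")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def column(self, otu_id: str) -> np.ndarray:
        return self.states[:, self.otu_ids.index(otu_id)]


def fit_step(values: np.ndarray) -> StepFit:
    """Fit a step-up function to one microbe's values.

    Values are sorted ascending internally; for every split k in 1..n-1 the
    side means m1, m2 and the step SSE are computed and the smallest-SSE
    split wins (smallest k on ties, for determinism).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < MIN_SAMPLES:
        raise InsufficientDataError(f"need >= {MIN_SAMPLES} values, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if x[-1] - x[0] == 0:
        return StepFit(float(x[0]), n // 2, float(x[0]), float(x[0]), 0.0, degenerate=True)

    # SSE(k) = sum(x^2) - k*m1(k)^2 - (n-k)*m2(k)^2, via prefix sums
    csum = np.cumsum(x)
    total = csum[-1]
    sq_total = float(np.sum(x * x))
    k = np.arange(1, n)
    m1 = csum[:-1] / k
    m2 = (total - csum[:-1]) / (n - k)
    sse = sq_total - k * m1**2 - (n - k) * m2**2
    best = int(np.argmin(sse))  # argmin returns the first minimum: smallest k
    bk = int(k[best])
    bm1, bm2 = float(m1[best]), float(m2[best])
    return StepFit(
        threshold=(bm1 + bm2) / 2.0,
        step_index=bk,
        left_mean=bm1,
        right_mean=bm2,
        sse=max(float(sse[best]), 0.0),  # clamp tiny negative round-off
        degenerate=False,
    )


def discretize(
    values: np.ndarray, fit: StepFit, params: DiscretizationParams = DiscretizationParams()
) -> np.ndarray:
    """Call each value low / intermediate / high around ``fit.threshold``.

    Values strictly above t + margin are high, strictly below t - margin are
    low; everything else — including values exactly on either boundary — is
    intermediate.  A degenerate fit yields an all-intermediate vector.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, INTERMEDIATE, dtype=np.uint8)
    if fit.degenerate:
        return out
    t, m = fit.threshold, params.margin
    out[x > t + m] = HIGH
    out[x < t - m] = LOW
    return out


def threshold_matrix(
    am, params: DiscretizationParams = DiscretizationParams()
) -> tuple[dict[str, StepFit], DiscreteMatrix]:
    """Fit one step per OTU of an abundance matrix and discretize all samples."""
    if am.n_samples < MIN_SAMPLES:
        raise InsufficientDataError(
            f"need >= {MIN_SAMPLES} samples, got {am.n_samples}"
        )
    fits: dict[str, StepFit] = {}
    states = np.empty((am.n_samples, am.n_otus), dtype=np.uint8)
    degenerate: set[str] = set()
    for j, otu in enumerate(am.otu_ids):
        f = fit_step(am.values[:, j])
        fits[otu] = f
        if f.degenerate:
            degenerate.add(otu)
        states[:, j] = discretize(am.values[:, j], f, params)
    return fits, DiscreteMatrix(states, list(am.sample_ids), list(am.otu_ids), degenerate)


def write_threshold_report(fits: dict[str, StepFit], path) -> None:
    """TSV report: otu_id, threshold, m1, m2, sse, degenerate."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("otu_id\tthreshold\tm1\tm2\tsse\tdegenerate\n")
        for otu, f in fits.items():
            fh.write(
                f"{otu}\t{f.threshold:.6g}\t{f.left_mean:.6g}\t{f.right_mean:.6g}"
                f"\t{f.sse:.6g}\t{str(f.degenerate).lower()}\n"
            )
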