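# Methods

## Model and assumptions

`boolimp` treats each microbe's log2 abundance across samples as
approximately two-state: a low mode (absent/rare) and a high mode
(established). A Boolean implication between microbes A and B is an
if-then constraint visible as one systematically under-populated quadrant
of their joint low/high scatter. The method assumes (i) per-microbe
bimodality strong enough for a step fit to separate the modes, (ii) that
samples within the noise margin of the threshold are unreliable and can be
dropped, and (iii) that the remaining counts in the four quadrants are
informative about the pair under an independence null with fixed marginals.
No compositional (closure) correction is applied; the statistics operate on
whatever normalization the input table carries.

## Procedure

1. **Transform.** Counts → log2(count + pseudocount), optionally after
   rescaling each sample to a fixed total depth.
2. **Threshold (StepMiner).** Per microbe, sort values and fit a one-step
   function by exhaustive search over splits k = 1..n−1, minimizing the sum
   of squared errors around the two side means; threshold t = (m1 + m2)/2.
   On sorted data only a step-up is possible, so no step-down fit is needed.
3. **Discretize.** value > t + margin → high, value < t − margin → low,
   else intermediate. Boundary values are intermediate.
4. **Classify pairs.** Tabulate non-intermediate samples into a00..a11 and
   test each quadrant: expected = row·col/total, S = (expected −
   observed)/√expected, error = ½(obs/row + obs/col); significant when
   S > s_min and error < err_max. One significant quadrant ⇒ the
   corresponding asymmetric implication (sparse (low,low) ⇒ A low → B high,
   the rest by symmetry); {q01,q10} ⇒ equivalent; {q00,q11} ⇒ opposite.
5. **FDR.** Shuffle every microbe's samples independently, n_perm rounds,
   rescan, FDR = mean permuted relationship count / original count
   (undefined when the original count is 0).
6. **Invariants.** Across k relation tables, keep pairs testable in every
   table with the identical kind everywhere.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| pseudocount | 1 | counts | keeps zero counts at log2 = 0 |
| scaling | none | — | input tables are treated as pre-normalized; `total_sum` optional |
| margin | 0.5 | log2 units | noise half-width around t |
| s_min | 3 | sd of a Poisson-like null | sparse-quadrant significance |
| err_max | 0.1 | fraction | max implication-violation rate |
| min_side_count / min_side_fraction | 3 / 0.05 | samples / fraction | dynamic-range filter per microbe |
| n_perm | 10 | rounds | permutation FDR |
| subset_size | 500 | microbes | correlation comparison subset |

`margin`, `s_min`, `err_max` and `n_perm` are the published operating
point. The **dynamic-range filter** is this package's addition: a microbe
must have at least max(min_side_count, min_side_fraction·n) low calls *and*
high calls to enter pair testing, because a near-constant microbe has one
quadrant pair empty by construction and would generate vacuous
"implications". Setting both knobs to 0 recovers a literal reading of the
significance rule alone.

## Design choices where the design was open

- **Threshold definition.** "Midpoint of the step" is implemented as
  (m1 + m2)/2 — the value at which the fitted step crosses between its two
  levels; unambiguous even with heavily tied data.
- **Tie-break.** Equal-SSE splits resolve to the smallest k, making fits
  deterministic.
- **Minimum n.** A step fit requires ≥ 4 values; matrices with fewer
  samples are rejected.
- **Degenerate microbes.** Zero-range vectors get a degenerate fit and an
  all-intermediate discretization; they fail the range filter and never
  reach pair testing. Undefined pair statistics (an empty marginal ⇒
  expected = 0) are reported as non-passing rather than raised, so all-pairs
  scans never abort.
- **Ambiguous quadrant combinations.** Any passing set other than a
  singleton, {q01,q10} or {q00,q11} (e.g. three sparse quadrants)
  classifies as `none`; such tables violate the implication model. The
  per-quadrant tests are retained on the record for audit.
- **Canonical pair order.** Records store the lexicographically smaller
  OTU id first; swapping axes maps low_low ↔ high_high and leaves
  low_high, high_low and the symmetric kinds fixed (contrapositive
  identity).
- **FDR optimization.** Step thresholds are provably invariant under
  per-microbe permutation (the fit sees sorted values only), so permutation
  rounds shuffle the discretized states directly instead of refitting; the
  range-filter outcome is likewise invariant because low/high counts are
  preserved.
- **Correlation scale.** Pearson r is computed on log2 values over *all*
  samples (the scale of the scatter plots); intermediates are not excluded,
  since correlation is the comparison method, not the implication test.
- **t-test flavor.** The metadata differential uses Welch's unequal-variance
  t-test by default (`equal_var=True` switches to Student's); ranking is
  descending −log10(p), ties broken by |mean difference| — a documented
  stand-in for what is fundamentally a visual selection step.
- **Invariant semantics.** "Consistent in every dataset" requires the pair
  to be *testable* in every dataset (both microbes pass the range filter)
  and to carry the identical kind in each; pairs untestable somewhere are
  tallied separately, not counted as inconsistent.

## Synthetic data: what it emulates and what it does not

The generator plants pairs directly in quadrant space: each sample draws a
quadrant from a categorical distribution whose sparse cell(s) hold only a
small leak mass (default 2%), then takes normal draws around a low mode
(4 log2 units) or high mode (8 log2 units) with sd 0.5 — a 4-unit
separation, i.e. strongly bimodal marginals. Values are back-transformed to
integer counts (⌊2^v − pseudocount⌉, floored at 0) so synthetic tables
exercise the same I/O and transform path as real ones. Decoy microbes are
independent: unimodal, independently bimodal, or shuffled copies of planted
columns (default alternates unimodal/shuffled). Multi-cohort generation
jitters sample count (±25%) and noise sd (±20%) around a shared truth.

Deliberately **not** modeled: 16S compositionality, correlations among
decoys, taxon abundance skew, and sequencing-depth artifacts. Passing the
planted-recovery tests therefore demonstrates detector correctness under
the model's own geometry, not performance on raw environmental data, where
weaker bimodality and compositional coupling will reduce power.

A consequence of the 2% leak worth knowing: in small cohorts (n ≈ 300) the
sparse quadrant of a planted asymmetric pair occasionally draws a
binomial-tail count whose error rate crosses 0.1, so the pair is honestly
non-significant in that cohort and drops out of the invariant intersection.
That is the statistic working as specified, not a detection bug.

## Problem sizes and numerical notes

The test-suite and reproduction-script simulations use 500-sample tables
with 2–30 microbes, 100 replicates per implication kind, and 10
permutations per FDR estimate — sizes at which every planted effect is
comfortably detectable and a full run takes seconds on one core. The step
fit computes SSE via prefix sums (O(n log n) including the sort) with the
SSE clamped at 0 against round-off; quadrant statistics are exact integer
arithmetic until the final division. All stochastic behavior flows from a
single integer seed per entry point, with per-microbe shuffles drawn in
fixed column order.

## Limitations

- Pair statistics ignore sample relatedness (repeated measures, nested
  studies) and treat samples as exchangeable.
- The independence expectation uses fixed marginals without continuity
  correction; very small tables (total < ~20) rarely reach S > 3, which is
  conservative by design.
- Correlation and implication are compared on the same data rather than
  held-out samples; the comparison is descriptive.
- No network construction on top of the pairwise relations; records are the
  final product.
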