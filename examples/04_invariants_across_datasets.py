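"""Nominate candidate universal invariants across four synthetic cohorts.

Four datasets share the same planted truth but differ in sample count and
noise level, emulating independent study pools.  A pair is an invariant
candidate only if it is testable in every dataset and carries the identical
implication kind everywhere.
"""

from boolimp import (
    PairSpec,
    RelationKind,
    find_invariants,
    generate_multidataset,
    scan_pairs,
    threshold_matrix,
    transform_log2,
)

planted = [PairSpec(RelationKind.EQUIVALENT), PairSpec(RelationKind.HIGH_LOW)]
sets = generate_multidataset(n_samples=500, n_microbes=12, planted=planted, k=4, seed=3)

tables = []
for i, (cm, _) in enumerate(sets):
    am = transform_log2(cm)
    _, dm = threshold_matrix(am)
    rt = scan_pairs(dm, dataset_id=f"cohort{i}")
    tables.append(rt)
    print(f"cohort{i}: n={cm.n_samples} samples, {len(rt.records)} relationships")

res = find_invariants(tables)
print(f"\n{len(res.invariants)} invariant(s) across all {len(tables)} cohorts:")
for v in res.invariants:
    print(f"  {v.otu_a} {v.kind.value:>10} {v.otu_b}")
print(f"({res.n_inconsistent} inconsistent, {res.n_untestable} untestable pairs)")
print("Both planted rules recur identically in every cohort, so both are")
print("nominated; decoy pairs never survive all four scans.")
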