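"""Classify one microbe pair from its 2x2 quadrant table.

The table below has almost no samples where both microbes are high
(a11 = 1), so "A high implies B low": the sparse-quadrant test compares the
observed corner count with what an independence model expects, via
S = (expected - observed) / sqrt(expected) and an error rate that measures
how often the implication is violated.  S > 3 and error < 0.1 is the
published significance rule.
"""

from boolimp import Quadrant, QuadrantCounts, classify_pair

q = QuadrantCounts(a00=50, a01=50, a10=50, a11=1)
rel = classify_pair(q)
print(f"table (a00,a01,a10,a11) = (50, 50, 50, 1), n_used = {q.n_used}")
print(f"classified kind: {rel.kind.value}   (A high -> B low)")
t = rel.test(Quadrant.Q11)
print(f"sparse quadrant q11: expected {t.expected:.3f}, observed {t.observed}, "
      f"S = {t.s_statistic:.3f}, error rate = {t.error_rate:.4f}")
print("S well above 3 with error below 0.1: the high-high corner is far")
print("emptier than chance, so high A levels almost always mean low B.")
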