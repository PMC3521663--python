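"""Predict absolute expression, constitutive and under simple repression.

Uses the thermodynamic occupancy model: expression = k * p_bound, with the
weak-promoter limit giving pure Boltzmann scaling, and a LacI-like
repressor (two binding heads, O2-strength operator) titrated on top.
"""

from promtune import (
    RepressionParams,
    ThermoParams,
    expression_constitutive,
    expression_repression,
    fold_change_repression,
)

tp = ThermoParams(k=870.0, dE_P=-4.2, p_over_nns=1e-3)
print(f"constitutive (weak limit): {expression_constitutive(tp, weak=True):8.2f}")
print(f"constitutive (full form) : {expression_constitutive(tp, weak=False):8.2f}")

print("\nrepressor titration (O2 operator, -13.9 kBT):")
print(f"{'R/cell':>8} {'fold-change':>12} {'expression':>11}")
for R in (0, 11, 30, 62, 130, 610, 900):
    rp = RepressionParams(R=R, dE_R=-13.9)
    fc = fold_change_repression(rp)
    print(f"{R:8d} {fc:12.4f} {expression_repression(tp, rp, weak=True):11.3f}")

# Expression falls monotonically with repressor count; the fold-change
# 1/(1 + 2R/N_NS * exp(-dE_R)) is promoter-independent in the weak limit,
# so the same curve rescales every promoter in the ladder.
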