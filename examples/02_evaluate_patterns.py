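"""Evaluate the ten interaction patterns A-J on one complex.

Uses a complex realizing the pattern combination reported for the
repositioning hit amodiaquine: a double pi-stacking sandwich plus
distal hydrophobic and halogen contacts, but no paired hydrogen bonds.
"""

from ipscreen import (FixtureSpec, PatternConfig, best_evaluation,
                      build_fixture)

fixture = build_fixture(FixtureSpec(patterns=frozenset("ABCDHJ")))
evaluation = best_evaluation(fixture.profile, PatternConfig())

print("pattern flags (base ring", evaluation.base_ring.member_serials, "):")
for p in "ABCDEFGHIJ":
    mark = "x" if evaluation.flags[p] else "."
    print(f"  {p} [{mark}]", end="")
    for ev in evaluation.evidence.get(p, [])[:1]:
        print(f"  e.g. {ev}", end="")
    print()
print(f"pattern count: {evaluation.count} / 10")

# A count of 6 with E-G false reproduces the amodiaquine-like profile:
# the ligand stacks on both ring faces and places distal probes inside
# the hydrophobic (4.0-6.5 A) and halogen (7.8-9.2 A) bands, without the
# paired hydrogen bonds of the nucleoside binders.
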