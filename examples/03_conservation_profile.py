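"""Profile a paralogue's damage to cross-species conserved positions.

Builds a 27-row orthologue alignment with planted conservation depths
(primates / mammals / tetrapods / vertebrates), derives a paralogue carrying
four variants at conserved columns, and reports each variant's clade depth
and whether the exchange is conservative or radical.
"""

from parapep import (
    conserved_columns,
    mutate_reference_paralogue,
    profile_paralogue_variants,
    simulate_orthologue_msa,
)

msa, clades, truth = simulate_orthologue_msa(seed=11)
conserved = conserved_columns(msa, clades, min_fraction=1.0)
n_by_depth = {}
for d in conserved.depth:
    if d:
        n_by_depth[d] = n_by_depth.get(d, 0) + 1
print("conserved columns by deepest clade:", n_by_depth)

paralogue, planted = mutate_reference_paralogue(msa, "primate_1", truth, n_saavs=4, seed=11)
profile = profile_paralogue_variants(paralogue, msa, "primate_1", conserved)

print(f"\nvariants of {profile.paralogue_id} at conserved columns:")
for s in profile.saavs:
    kind = "conservative" if s.conservative else "radical"
    print(f"  {s.name:<8} column {s.column:<4} conserved across {s.clade_depth:<12} {kind}")
print(
    "\nSAAV totals by clade depth (deeper-conserved columns are fewer, so "
    "totals can only shrink):",
    profile.saav_totals,
)
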