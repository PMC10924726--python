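"""Decide which member of a paralogue family the peptide evidence supports.

Simulates a five-copy family (one intact coding copy, four derived copies
with shared and private variants), builds its evidence table, applies the
quality filters (no singletons, <=2 missed cleavages), maps every peptide
onto every copy and ranks the copies by explained-observation fraction.
"""

from parapep import (
    FamilySpec,
    apply_rescue,
    build_attribution,
    explain_unmapped,
    filter_peptide_table,
    simulate_family,
    simulate_peptide_table,
)

spec = FamilySpec(seed=1)
family = simulate_family(spec)
observations = simulate_peptide_table(family.truth, spec)
filtered = filter_peptide_table(observations, min_obs=2, max_missed=2)

print(f"evidence table: {len(observations)} peptides, "
      f"{sum(o.n_obs for o in observations)} observations "
      f"({len(observations) - len(filtered)} removed by filters)")

report = build_attribution(filtered, family.proteins)
target = next(p for p in family.proteins if p.id == report.top.protein_id)
unmapped = [o for o in filtered if o.peptide in dict(report.unmapped)]
report = apply_rescue(report, explain_unmapped(unmapped, target, evidence=filtered))

print(f"\n{'copy':<10}{'captured':>9}{'unique':>8}{'obs frac':>10}{'+variants':>11}")
for e in report.paralogues:
    print(
        f"{e.protein_id:<10}{len(e.captured):>9}{len(e.unique):>8}"
        f"{e.explained_fraction:>10.4f}{e.variant_inclusive_fraction:>11.4f}"
    )
print(
    f"\ntop-ranked copy {report.top.protein_id} "
    f"(truth: {family.truth.coding_id}); its unique peptides are windows where "
    "every sibling carries a shared or private variant, and the variant-"
    "inclusive fraction folds in rescued allele peptides."
)
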