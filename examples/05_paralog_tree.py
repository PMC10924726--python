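"""Test the duplication history of a paralogue family with TN93 + NJ.

The family's derived copies duplicate from an already-diverged intermediate
ancestor, so on a tree rooted with an outgroup species they should form
their own clade, separate from the coding copy — the topological signature
that the suspect copies share a common (pseudogenising) origin.
"""

from parapep import FamilySpec, nj_tree, simulate_family, tn93_matrix

family = simulate_family(FamilySpec(seed=1))
dm = tn93_matrix(family.cds_aligned)
print("taxa:", ", ".join(dm.taxa))
print(f"max pairwise TN93 distance: {dm.values.max():.4f} substitutions/site")

tree = nj_tree(dm, outgroup="outgroup_1")
print("\nrooted tree:", tree.as_string(schema="newick").strip())

siblings = frozenset(
    t
    for t in family.cds_aligned
    if t != family.truth.coding_id and not t.startswith("outgroup")
)
is_clade = any(
    frozenset(l.taxon.label for l in node.leaf_iter()) == siblings for node in tree
)
print(
    f"\nderived copies {sorted(siblings)} form their own clade: {is_clade} "
    f"(coding copy {family.truth.coding_id} stays outside it)"
)
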