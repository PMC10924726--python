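"""Classify transcript lesions relative to a parent CDS and combine them
with peptide evidence into coding/pseudogene verdicts.

Four transcripts are compared against an intact parent: an identical copy,
one with a point mutation to TAA, one with a 4-base frameshifting deletion,
and one missing its first 50 codons (a lost 5' exon).
"""

from parapep import assess_transcript, classify_gene
from parapep.tryptic import ParalogueEvidence

body = ("GCT", "GGT", "ACT", "CTG", "GAA", "TCC")
parent = "".join(["ATG"] + [body[i % 6] for i in range(98)] + ["TAA"])

transcripts = {
    "intact_copy": parent,
    "stop_copy": parent[:150] + "TAA" + parent[153:],
    "frameshift_copy": parent[:100] + parent[104:],
    "truncated_copy": parent[150:],
}

print(f"{'transcript':<17}{'status':<20}lesions")
statuses = {}
for name, seq in transcripts.items():
    st = assess_transcript(seq, parent, transcript_id=name)
    statuses[name] = st
    lesions = "; ".join(f"{l.kind}@{l.cds_position}" for l in st.lesions) or "-"
    print(f"{name:<17}{st.status:<20}{lesions}")


def evidence(pid, n_unique):
    return ParalogueEvidence(
        protein_id=pid, captured=("PEPK",) * bool(n_unique),
        unique=("PEPK",) * n_unique, captured_obs=0, unique_obs=0,
        explained_fraction=0.0, variant_inclusive_fraction=0.0,
    )


print("\nverdicts (lesion status x peptide evidence):")
print("  intact + 1 unique peptide           ->",
      classify_gene(statuses["intact_copy"], evidence("intact_copy", 1)))
print("  intact + none, sibling explains 99% ->",
      classify_gene(statuses["intact_copy"], evidence("intact_copy", 0),
                    sibling_best_fraction=0.9998))
print("  premature stop                      ->",
      classify_gene(statuses["stop_copy"], evidence("stop_copy", 0)))
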