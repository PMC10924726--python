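"""Explain an unmapped peptide as a single-amino-acid variant, and count
alleles at the variant position across a haplotype panel.

The scenario mirrors a common-variant discovery: a heavily observed peptide
maps to no paralogue, but differs from the top copy's sequence at exactly
one residue (a G->S change); a panel of predicted haplotype proteins then
shows both alleles segregating at that position.
"""

from parapep import (
    PeptideObservation,
    ProteinRecord,
    explain_unmapped,
    rescue_single_substitution,
    summarize_haplotype_alleles,
)

target = ProteinRecord(id="copyA", sequence="MKQDDGSSSASPSVQGAPRLLK")
evidence = [
    PeptideObservation("QDDGSSSASPSVQGAPR", 1999),  # maps exactly
    PeptideObservation("QDDSSSSASPSVQGAPR", 1239),  # maps nowhere
]

(hit,) = rescue_single_substitution("QDDSSSSASPSVQGAPR", target)
print(
    f"unmapped peptide explained as {hit.ref_residue}{hit.protein_position}"
    f"{hit.obs_residue} on {hit.protein_id} "
    f"(window starts at residue {hit.window_start})"
)

partition = explain_unmapped([evidence[1]], target, evidence=evidence)
(windows,) = partition.explained.values()
print(
    f"corroborating exact counterpart in the evidence table: "
    f"{windows[0].supporting_exact_peptide}"
)
print(f"observations attributable to the variant: {partition.explained_obs}")

# haplotype panel: 17 glycine / 16 serine alleles at the rescued position
panel = ["MKQDDGSSSASPSVQGAPRLLK"] * 17 + ["MKQDDSSSSASPSVQGAPRLLK"] * 16
count = summarize_haplotype_alleles(panel, hit.protein_position)
print(
    f"alleles at position {count.column} over {count.n_sequences} haplotypes: "
    + ", ".join(f"{aa}={n}" for aa, n in sorted(count.counts.items()))
    + "  -> a common segregating variant, not a second translated gene"
)
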