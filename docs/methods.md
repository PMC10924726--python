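# Methods

## The inference problem

A family of paralogues with near-identical predicted proteins is observed
through a peptide evidence table: each detected peptide carries a count of
distinct observations across many experiments, used here as a rough
expression proxy. Because most peptides lie in regions where several copies
are identical, raw capture counts overstate the support for every copy. The
decisive evidence is (i) peptides unique to one copy, (ii) the fraction of
all observations a copy explains, (iii) single-amino-acid-variant peptides
attributable to a common allele of that copy rather than to a second
translated gene, (iv) the damage each copy shows at positions conserved
across deep clades, and (v) disabling lesions in each copy's transcript.
`parapep` computes all five and combines them into per-gene verdicts.

## Digestion and mapping

Trypsin cleaves after K or R. The proline rule (K/R followed by P is not
cleaved) is on by default, matching common search-engine settings, and can
be disabled; both modes are tested. A peptide is fully tryptic on a protein
when its N-boundary is the protein start or follows a cleavage-competent
K/R and its C-boundary is the protein end or a cleavage-competent K/R.
Missed cleavages are cleavage-competent K/R internal to the peptide; the
C-terminal residue never counts. Evidence filters: observations ≥ 2 (drop
singletons) and missed cleavages ≤ 2; the fully-tryptic requirement is
enforced at mapping time because boundaries depend on protein context.
Enumeration defaults to the 7–50 residue window typical of detectable
tryptic peptides; mapping imposes no length window of its own.

Isoleucine and leucine are distinct by default — discriminating paralogues
by single residues requires it — with an optional I=L mode reflecting their
isobaric mass. Sequences may contain X (unknown); any peptide or window
containing X never matches. A peptide occurring at two positions in one
protein counts once toward that protein's capture set.

Ranking of copies is by descending explained-observation fraction; ties
break by larger unique-observation total, then lexicographic id, making the
report invariant to input order.

## Variant rescue

Only single substitutions are rescued — no indels, no double variants —
because anything more permissive floods near-identical families with false
explanations. Trypticity and the missed-cleavage budget are re-evaluated on
the substituted sequence, so substitutions that create or destroy a K/R (or
a suppressing proline) are handled correctly. When several windows explain
one peptide all are reported, but its observations count once. Each rescue
is cross-checked against the evidence table for the unsubstituted
counterpart peptide; a counterpart found corroborates the variant, its
absence is not disqualifying. The variant-inclusive explained fraction is
by construction ≥ the exact-only fraction.

## Conservation profiling

Clade levels nest: primates ⊂ mammals ⊂ tetrapods ⊂ vertebrates. A column
is conserved at a level when, among rows inside that clade, gaps are within
tolerance and the modal residue reaches `min_fraction`. Defaults are strict
(identity, zero gaps) because the notion of "conserved" should err
conservative when calling damage; both knobs are configurable, and recorded
depth is the deepest level of the unbroken chain from the shallowest clade,
which keeps depth monotone under lax settings too.

The orthologue-inclusion rule drops candidates with any insertion or
deletion run longer than 7 columns against the reference, or missing the
reference's first/last aligned residues (the ancestral termini).

Substitutions are conservative iff both residues share a fixed exchange
group — {AGPST}, {ILMV}, {DENQ}, {KRH}, {FWY}, {C} — a standard
physicochemical grouping pinned in code for determinism. Paralogues are
aligned to the ungapped reference row by global alignment (BLOSUM62, gap
open −11, extend −1); variant names like G343S use the paralogue's own
1-based residue numbering. SAAVs are reported only at conserved columns
(differences at unconstrained positions carry no signal about damage);
deletions and insertions are reported everywhere. Shared derived variants
across profiles can pool different alternate residues at one column
(reported like Y141D/E), since a column recurrently hit in several copies
marks common descent regardless of the exact exchange.

## Coding status

Transcripts align to the parent CDS globally with free end gaps
(match +2, mismatch −3, gap open −7, extend −2), so a 5′-truncated
transcript is not penalised for the parent overhang. Lesions:

* **premature stop** — a stop codon read in the parent frame upstream of
  the parent's stop. "In frame" requires the codon to be gaplessly aligned
  to a parent codon with the cumulative indel offset ≡ 0 (mod 3); stops
  downstream of a frameshift are out of frame and deliberately not
  reported as stops.
* **frameshift** — an indel whose length is not divisible by 3. In-frame
  indels alter the protein without scrambling it and are not lesions.
* **5′ truncation** — alignment starting ≥ 50 codons (configurable) into
  the parent, the size of a typical lost first coding exon.
* **fragment** — aligned coverage below 50% of the parent (configurable;
  "full length" has no canonical numeric definition, so the threshold is a
  package choice).

Status reports the most consequential lesion (fragment, stop, frameshift,
truncation) and is `full_length_intact` exactly when the lesion list is
empty. Verdicts: any disabling lesion → pseudogene; intact with ≥ 1 unique
peptide → coding; a truncated copy is coding only if unique peptides
support the retained region; an intact copy with no unique peptides is
ambiguous unless some sibling's variant-inclusive fraction reaches 0.99
(configurable), in which case it is a pseudogene by comparison — absence
of evidence alone never makes the call, but near-total attribution to a
sibling does.

## Distances and trees

TN93 distinguishes the two transition classes (A↔G, C↔T) from
transversions and uses the empirical base frequencies of each pair pooled
over comparable sites; sites with gaps or ambiguity codes in either
sequence are excluded pairwise, and a non-positive logarithm argument
(saturation) yields infinity. Neighbor-joining uses the standard Q
criterion with a deterministic lexicographic tie-break; trees are unrooted
unless an outgroup is supplied, in which case the root bisects the
outgroup's pendant edge. This distance pipeline is a deliberate topological
stand-in for full maximum-likelihood phylogenetics: the question asked of
it — do the suspect copies form their own clade? — is about topology, not
branch support, so no invariant-sites parameter and no bootstrapping are
implemented.

## The synthetic generator

`simulate_family` emulates the study system's structure, not any particular
sequences. An ancestral protein (default 450 residues, uniform composition,
~10% K/R so tryptic peptides average ~10 residues) is encoded into codons
once; the coding copy keeps it intact. Non-coding copies descend from an
*intermediate* ancestor carrying shared derived SAAVs (rate 0.01/residue,
conditioned ≥ 1) and a shared 3-residue deletion — this shared-derived
block is what gives the coding copy unique peptides and makes the siblings
a clade, mirroring families that duplicate from an already-diverged,
pseudogenising source. Each copy then adds private SAAVs (rate 0.01),
optionally a 1–3 residue deletion (probability 0.3), and CDS lesions:
premature stop (probability 0.6), frameshifting 1/2/4-nt deletion (0.3),
50-codon 5′ truncation (0.15). Codons are inherited, never re-drawn, so
nucleotide distances reflect the duplication history; two outgroup species
at 5% nucleotide divergence from the ancestor are emitted for tree tests.

The evidence table samples a log-normal observation count (ln-mean 3.0,
ln-sd 1.5 — heavy-tailed, spanning single digits to a few thousand, with
total depth well above 500) for every fully tryptic peptide of the coding
copy (0–2 missed cleavages, 7–50 residues). One heterozygous allele
(frequency 0.5) splits covering peptides binomially into ref/alt versions;
allele positions avoid K, R and P (a variant at a cleavage site would
produce different fragments entirely, which the model does not emulate) and
are restricted to residues some detectable peptide covers, since an allele
in an undetectable region could leave no evidence. Five contaminant
singletons exercise the observation filter. All randomness flows from the
spec's single seed through named generators; no global state.

`simulate_orthologue_msa` plants each column either conserved to a chosen
depth — identical within the clade and broken by construction one ring
further out — or variable even among primates, and returns the planted
truth, so strict-mode recovery can be checked exactly.

**What the generator does not emulate:** spectral-level noise and false
peptide-spectrum matches beyond singleton contaminants, semi-tryptic
peptides, I/L ambiguity in real search output, indel variants, alignment
uncertainty in the orthologue panel, rate heterogeneity across sites, and
genomic context (exon structure, synteny). Passing tests therefore show the
inference machinery is correct under the stated evidence model, not that
real evidence tables are this clean.

## Numerical and design notes

* Coordinates are 1-based inclusive everywhere.
* Duplicate rows in a peptide table aggregate by summing counts
  (order-independently), so per-experiment exports behave like
  per-peptide exports.
* Report JSON is schema-versioned and round-trips exactly; ranking
  tie-breaks, alignment parameters and exchange groups are pinned.
* NJ tie-breaks compare candidate pairs by the lexicographically smallest
  leaf label of each cluster; equal-Q candidates within 1e-12 are treated
  as ties. Negative NJ branch lengths are reported as computed.
* TN93 degenerate compositions (no purines or no pyrimidines at comparable
  sites, with differences present) return infinity rather than a guess.
* Problem sizes in the test-suite and acceptance script (1000 oracle
  proteins, 200 families, 100 rescue seeds, 50 conservation panels, 60
  tree replicates) were chosen to give stable rate estimates while keeping
  a full run in seconds.

## Limitations

The pipeline starts from peptide-level evidence; it does not rescore
spectra or model FDR, and protein inference is unique-peptide attribution
only (no parsimony across shared peptides). Panel assembly for haplotype
allele counting is up to the user. Exon-level reasoning is approximated on
CDS sequences; genomic annotation formats are out of scope. The comparative
pseudogene verdict is a heuristic encoding of "a sibling already explains
essentially everything" and should be read alongside the conservation
profile, not instead of it.
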