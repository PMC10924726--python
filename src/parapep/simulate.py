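"""Synthetic paralogue families, evidence tables and orthologue alignments
with recorded ground truth.

The generator emulates the study system: a family of near-identical protein
paralogues in one genome, exactly one of which (the designated coding copy)
keeps the ancestral sequence intact and is actually translated. The
remaining copies do not descend from the coding copy directly — they
duplicate from an *already-diverged* intermediate ancestor, so they share a
block of derived single-amino-acid variants and a short deletion, on top of
copy-specific variants and disabling CDS lesions (premature stops,
frameshifting deletions, 5' truncations). This shared-derived structure is
what gives the coding copy unique peptides (windows where every sibling
differs) and what makes the siblings their own clade in a phylogeny, apart
from the coding copy and outgroup species.

The evidence table contains the coding copy's fully tryptic peptides with
heavy-tailed observation counts, splits peptides overlapping a heterozygous
protein allele into reference/alternate versions by allele frequency, and
plants rare contaminant singletons that the quality filter should remove.
All randomness flows from the spec's single seed; the same seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .conservation import ConservedColumnSet
from .io import CLADE_LEVELS, CladeMap, PeptideObservation, ProteinRecord, ValidationError
from .tryptic import enumerate_tryptic_peptides

__all__ = [
    "FamilySpec",
    "PlantedAllele",
    "SyntheticTruth",
    "Family",
    "simulate_family",
    "simulate_peptide_table",
    "simulate_orthologue_msa",
    "mutate_reference_paralogue",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: residues safe for heterozygous alleles: not cleavage sites and not
#: proline, so both allele peptides stay fully tryptic
_ALLELE_SAFE = "".join(aa for aa in _AA20 if aa not in "KRP")
_NT = "ACGT"

_CODONS_OF: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_OF.setdefault(aa, []).append(codon)
for aa in _CODONS_OF:
    _CODONS_OF[aa].sort()


@dataclass(frozen=True)
class PlantedAllele:
    """A heterozygous protein-level allele on the coding copy."""

    position: int  # 1-based residue on the coding copy
    ref: str
    alt: str
    frequency: float  # population frequency of the alternate allele


@dataclass(frozen=True)
class FamilySpec:
    """Study conditions for one synthetic paralogue family.

    Defaults mirror the scale of the real system: five near-identical
    copies of a ~450-residue protein; an intermediate ancestor of the
    non-coding copies carrying ~1% shared derived SAAVs plus a 3-residue
    deletion; ~1% further copy-specific divergence; most derived copies
    with a disabling lesion; one common heterozygous allele on the coding
    copy; a handful of contaminant singletons; log-normal observation
    counts spanning a few to a few thousand; and two outgroup species at
    ~5% nucleotide divergence for tree tests.
    """

    seed: int = 0
    n_paralogues: int = 5
    protein_length: int = 450
    shared_saav_rate: float = 0.01
    shared_deletion_len: int = 3
    saav_rate: float = 0.01
    indel_rate: float = 0.3
    indel_max_len: int = 3
    stop_probability: float = 0.6
    frameshift_probability: float = 0.3
    truncation_probability: float = 0.15
    truncation_codons: int = 50
    coding_index: int = 0
    het_frequency: float = 0.5
    n_het_alleles: int = 1
    n_contaminants: int = 5
    obs_log_mean: float = 3.0
    obs_log_sigma: float = 1.5
    n_outgroups: int = 2
    outgroup_divergence: float = 0.05
    min_peptide_len: int = 7
    max_peptide_len: int = 50

    def __post_init__(self) -> None:
        for name in (
            "shared_saav_rate",
            "saav_rate",
            "indel_rate",
            "stop_probability",
            "frameshift_probability",
            "truncation_probability",
            "het_frequency",
            "outgroup_divergence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.coding_index < self.n_paralogues:
            raise ValidationError("coding_index outside the paralogue range")
        if self.n_paralogues < 1 or self.protein_length < 30:
            raise ValidationError("need >=1 paralogue of length >=30")


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated family, verifiable against the outputs.

    Positions are 1-based; SAAV and deletion coordinates refer to the
    ancestral (= coding copy) protein.
    """

    coding_id: str
    coding_sequence: str
    shared_saavs: tuple[tuple[int, str, str], ...]  # (pos, ref, alt) on the intermediate
    shared_deletion: tuple[int, int] | None  # (pos, length)
    lesions: dict[str, tuple[tuple[str, int], ...]]  # copy -> ((kind, own-CDS pos), ...)
    copy_saavs: dict[str, tuple[tuple[int, str, str], ...]]  # copy-specific, ancestor coords
    copy_deletions: dict[str, tuple[tuple[int, int], ...]]  # (pos, length), ancestor coords
    alleles: tuple[PlantedAllele, ...]
    peptide_labels: dict[str, str] = field(default_factory=dict)  # peptide -> label


@dataclass
class Family:
    proteins: list[ProteinRecord]
    cds: dict[str, str]  # unaligned CDS per copy, lesions included
    cds_aligned: dict[str, str]  # copies + outgroups in ancestor codon coordinates
    ancestral_protein: str
    ancestral_cds: str
    truth: SyntheticTruth


def _random_codon(aa: str, rng: np.random.Generator) -> str:
    codons = _CODONS_OF[aa]
    return codons[rng.integers(len(codons))]


def simulate_family(spec: FamilySpec) -> Family:
    """Generate one paralogue family: protein records, CDS sequences, an
    ancestor-coordinate nucleotide alignment (with outgroup species) and
    the ground truth.

    The designated coding copy keeps the ancestral protein and an intact
    CDS; lesion probabilities never apply to it. Non-coding copies inherit
    the intermediate ancestor's shared SAAVs (at least one) and shared
    deletion, then add copy-specific SAAVs, optional small deletions, and
    CDS-level lesions. Codons are inherited, not re-drawn, so nucleotide
    distances reflect the duplication history. The aligned set contains
    SAAVs, planted stop codons and deletions (as gap columns) but not
    frameshifts or 5' truncations, which are meaningful only on the
    unaligned CDS.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.protein_length
    ancestor = "".join(_AA20[i] for i in rng.integers(0, 20, size=L))
    anc_codons = [_random_codon(aa, rng) for aa in ancestor] + ["TAA"]
    ancestral_cds = "".join(anc_codons)

    ids = [f"para{i + 1:02d}" for i in range(spec.n_paralogues)]
    coding_id = ids[spec.coding_index]

    # --- intermediate (already-diverged) ancestor of the non-coding copies --
    n_shared = max(1, int(rng.binomial(L, spec.shared_saav_rate)))
    shared_pos = sorted(int(p) for p in rng.choice(L, size=n_shared, replace=False))
    shared_saavs = []
    inter_codons: list[str | None] = list(anc_codons)
    for pos in shared_pos:
        ref = ancestor[pos]
        choices = [aa for aa in _AA20 if aa != ref]
        alt = choices[rng.integers(len(choices))]
        inter_codons[pos] = _random_codon(alt, rng)
        shared_saavs.append((pos + 1, ref, alt))
    shared_deletion = None
    if spec.shared_deletion_len > 0:
        dlen = spec.shared_deletion_len
        while True:
            dpos = int(rng.integers(L // 10, (9 * L) // 10))
            if all(p - 1 not in range(dpos, dpos + dlen) for p, _, _ in shared_saavs):
                break
        for k in range(dpos, dpos + dlen):
            inter_codons[k] = None
        shared_deletion = (dpos + 1, dlen)

    proteins: list[ProteinRecord] = []
    cds: dict[str, str] = {}
    cds_aligned: dict[str, str] = {}
    lesions: dict[str, tuple[tuple[str, int], ...]] = {}
    copy_saavs: dict[str, tuple[tuple[int, str, str], ...]] = {}
    copy_deletions: dict[str, tuple[tuple[int, int], ...]] = {}

    for idx, copy_id in enumerate(ids):
        if idx == spec.coding_index:
            proteins.append(
                ProteinRecord(id=copy_id, sequence=ancestor, description="coding copy")
            )
            cds[copy_id] = ancestral_cds
            cds_aligned[copy_id] = ancestral_cds
            lesions[copy_id] = ()
            copy_saavs[copy_id] = ()
            copy_deletions[copy_id] = ()
            continue
        codons: list[str | None] = list(inter_codons)
        # --- copy-specific SAAVs ----------------------------------------
        available = [k for k in range(L) if codons[k] is not None]
        n_spec = min(int(rng.binomial(L, spec.saav_rate)), len(available))
        saavs = []
        if n_spec:
            picked = sorted(
                int(available[i])
                for i in rng.choice(len(available), size=n_spec, replace=False)
            )
            for pos in picked:
                cur = standard_dna_table.forward_table[codons[pos]]
                choices = [aa for aa in _AA20 if aa != cur]
                alt = choices[rng.integers(len(choices))]
                codons[pos] = _random_codon(alt, rng)
                saavs.append((pos + 1, cur, alt))
        # --- copy-specific small deletion -------------------------------
        dels: list[tuple[int, int]] = []
        if rng.random() < spec.indel_rate:
            dlen = int(rng.integers(1, spec.indel_max_len + 1))
            runs = [
                k
                for k in range(L - dlen)
                if all(codons[k + j] is not None for j in range(dlen))
            ]
            if runs:
                dpos = int(runs[rng.integers(len(runs))])
                for j in range(dlen):
                    codons[dpos + j] = None
                dels.append((dpos + 1, dlen))
        protein = "".join(
            standard_dna_table.forward_table[c] for c in codons[:-1] if c is not None
        )
        proteins.append(
            ProteinRecord(id=copy_id, sequence=protein, description="derived copy")
        )
        copy_saavs[copy_id] = tuple(saavs)
        copy_deletions[copy_id] = tuple(dels)
        # --- CDS lesions --------------------------------------------------
        copy_lesions: list[tuple[str, int]] = []
        present = [k for k in range(L) if codons[k] is not None]
        if rng.random() < spec.stop_probability:
            k = present[int(rng.integers(len(present) // 10, (9 * len(present)) // 10))]
            codons[k] = "TAA"
            stop_nt = 3 * sum(1 for j in present if j < k)
            copy_lesions.append(("premature_stop", stop_nt + 1))
        copy_cds = "".join(c for c in codons if c is not None)
        cds_aligned[copy_id] = "".join(c if c is not None else "---" for c in codons)
        if rng.random() < spec.frameshift_probability:
            fs_len = int(rng.choice([1, 2, 4]))
            fs_pos = int(rng.integers(3, len(copy_cds) - fs_len - 3))
            copy_cds = copy_cds[:fs_pos] + copy_cds[fs_pos + fs_len :]
            copy_lesions.append(("frameshift", fs_pos + 1))
        if rng.random() < spec.truncation_probability:
            copy_cds = copy_cds[spec.truncation_codons * 3 :]
            copy_lesions.append(("truncated_5prime", 1))
        cds[copy_id] = copy_cds
        lesions[copy_id] = tuple(copy_lesions)

    # --- outgroup species for tree tests -----------------------------------
    for j in range(spec.n_outgroups):
        seq = list(ancestral_cds)
        hits = rng.random(len(seq)) < spec.outgroup_divergence
        for k in np.flatnonzero(hits):
            alts = [b for b in _NT if b != seq[k]]
            seq[int(k)] = alts[rng.integers(3)]
        cds_aligned[f"outgroup_{j + 1}"] = "".join(seq)

    # --- heterozygous alleles on the coding copy --------------------------
    # planted only at residues some detectable tryptic peptide covers: an
    # allele in an undetectable region could never leave peptide evidence
    covered = set()
    for pep, start in enumerate_tryptic_peptides(
        ancestor,
        max_missed=2,
        min_len=spec.min_peptide_len,
        max_len=spec.max_peptide_len,
    ):
        covered.update(range(start - 1, start - 1 + len(pep)))
    alleles: list[PlantedAllele] = []
    safe_positions = [
        i for i, aa in enumerate(ancestor) if aa in _ALLELE_SAFE and i in covered
    ]
    for _ in range(spec.n_het_alleles):
        pos = int(safe_positions[rng.integers(len(safe_positions))])
        ref = ancestor[pos]
        choices = [aa for aa in _ALLELE_SAFE if aa != ref]
        alt = choices[rng.integers(len(choices))]
        alleles.append(
            PlantedAllele(position=pos + 1, ref=ref, alt=alt, frequency=spec.het_frequency)
        )

    truth = SyntheticTruth(
        coding_id=coding_id,
        coding_sequence=ancestor,
        shared_saavs=tuple(shared_saavs),
        shared_deletion=shared_deletion,
        lesions=lesions,
        copy_saavs=copy_saavs,
        copy_deletions=copy_deletions,
        alleles=tuple(alleles),
    )
    return Family(
        proteins=proteins,
        cds=cds,
        cds_aligned=cds_aligned,
        ancestral_protein=ancestor,
        ancestral_cds=ancestral_cds,
        truth=truth,
    )


def simulate_peptide_table(
    truth: SyntheticTruth, spec: FamilySpec
) -> list[PeptideObservation]:
    """PeptideAtlas-style evidence table for a simulated family.

    Enumerates the coding copy's fully tryptic peptides (0–2 missed
    cleavages, length window from the spec), samples a log-normal
    observation count for each, splits peptides covering a heterozygous
    allele into reference/alternate versions binomially by allele
    frequency, and appends contaminant singletons. Every emitted row is
    labelled in ``truth.peptide_labels`` as coding / variant_allele /
    contaminant.
    """
    rng = np.random.default_rng([spec.seed, 1])
    coding = truth.coding_sequence
    pairs = sorted(
        enumerate_tryptic_peptides(
            coding,
            max_missed=2,
            min_len=spec.min_peptide_len,
            max_len=spec.max_peptide_len,
        )
    )
    counts: dict[str, int] = {}
    windows: dict[str, list[int]] = {}
    for pep, start in pairs:
        windows.setdefault(pep, []).append(start)
    for pep in sorted(windows):
        n = int(round(rng.lognormal(spec.obs_log_mean, spec.obs_log_sigma)))
        counts[pep] = max(1, n)

    labels: dict[str, str] = {}
    out_counts: dict[str, int] = {}
    for pep in sorted(counts):
        n = counts[pep]
        emitted = False
        for allele in truth.alleles:
            covering = [
                s for s in windows[pep] if s <= allele.position <= s + len(pep) - 1
            ]
            if not covering:
                continue
            s = covering[0]
            offset = allele.position - s
            alt_pep = pep[:offset] + allele.alt + pep[offset + 1 :]
            n_alt = int(rng.binomial(n, allele.frequency))
            n_ref = n - n_alt
            if n_ref > 0:
                out_counts[pep] = out_counts.get(pep, 0) + n_ref
                labels[pep] = "coding"
            if n_alt > 0:
                out_counts[alt_pep] = out_counts.get(alt_pep, 0) + n_alt
                labels[alt_pep] = "variant_allele"
            emitted = True
            break
        if not emitted:
            out_counts[pep] = out_counts.get(pep, 0) + n
            labels[pep] = "coding"

    existing = set(out_counts)
    for _ in range(spec.n_contaminants):
        while True:
            length = int(rng.integers(8, 16))
            body = "".join(
                _ALLELE_SAFE[i]
                for i in rng.integers(0, len(_ALLELE_SAFE), size=length - 1)
            )
            pep = body + ("K" if rng.random() < 0.5 else "R")
            if pep not in existing:
                break
        existing.add(pep)
        out_counts[pep] = 1
        labels[pep] = "contaminant"

    truth.peptide_labels = labels
    return [
        PeptideObservation(peptide=pep, n_obs=out_counts[pep])
        for pep in sorted(out_counts)
    ]


_DEFAULT_RING_SIZES = {"primates": 5, "mammals": 8, "tetrapods": 7, "vertebrates": 7}


def simulate_orthologue_msa(
    ring_sizes: Mapping[str, int] | None = None,
    conserved_fraction: float = 0.7,
    length: int = 120,
    seed: int = 0,
    reference_sequence: str | None = None,
) -> tuple[dict[str, str], CladeMap, ConservedColumnSet]:
    """Generate an orthologue alignment with planted conserved columns.

    ``ring_sizes`` gives the number of rows whose species sit exactly at
    each clade level (defaults emulate a ~27-species vertebrate panel).
    Each column is either conserved to a planted depth — identical within
    the clade, broken by construction one ring further out — or
    unconserved even among primates. When ``reference_sequence`` is given
    the first primate row equals it exactly (its residues become the
    column consensus), so a paralogue family built on that sequence can be
    profiled against the alignment. Returns the rows, the clade map and
    the planted truth; with strict scoring the recovered conservation
    equals the truth exactly.
    """
    if not 0.0 <= conserved_fraction <= 1.0:
        raise ValidationError("conserved_fraction must be in [0, 1]")
    sizes = dict(_DEFAULT_RING_SIZES if ring_sizes is None else ring_sizes)
    if sizes.get("primates", 0) < 2:
        raise ValidationError("need at least 2 primate rows")
    if reference_sequence is not None:
        if any(aa not in _AA20 for aa in reference_sequence):
            raise ValidationError("reference_sequence must use the 20 standard residues")
        length = len(reference_sequence)
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    levels: dict[str, str] = {}
    ring_of: dict[str, list[str]] = {}
    for level in CLADE_LEVELS:
        ring = [f"{level[:-1]}_{i + 1}" for i in range(sizes.get(level, 0))]
        ring_of[level] = ring
        for seq_id in ring:
            ids.append(seq_id)
            levels[seq_id] = level

    columns: dict[str, list[str]] = {i: [] for i in ids}
    depth: list[str | None] = []
    consensus: list[dict[str, str]] = []
    for col in range(length):
        if rng.random() < conserved_fraction:
            d = CLADE_LEVELS[rng.integers(len(CLADE_LEVELS))]
            cons = (
                reference_sequence[col]
                if reference_sequence is not None
                else _AA20[rng.integers(20)]
            )
            d_idx = CLADE_LEVELS.index(d)
            for level in CLADE_LEVELS[: d_idx + 1]:
                for seq_id in ring_of[level]:
                    columns[seq_id].append(cons)
            breaker_done = False
            for level in CLADE_LEVELS[d_idx + 1 :]:
                for k, seq_id in enumerate(ring_of[level]):
                    if not breaker_done and k == 0:
                        other = [aa for aa in _AA20 if aa != cons]
                        columns[seq_id].append(other[rng.integers(len(other))])
                        breaker_done = True
                    else:
                        columns[seq_id].append(_AA20[rng.integers(20)])
            depth.append(d)
            consensus.append({level: cons for level in CLADE_LEVELS[: d_idx + 1]})
        else:
            a = (
                reference_sequence[col]
                if reference_sequence is not None
                else _AA20[rng.integers(20)]
            )
            others = [aa for aa in _AA20 if aa != a]
            b = others[rng.integers(len(others))]
            for level in CLADE_LEVELS:
                for k, seq_id in enumerate(ring_of[level]):
                    if level == "primates" and k == 0:
                        columns[seq_id].append(a)
                    elif level == "primates" and k == 1:
                        columns[seq_id].append(b)
                    else:
                        columns[seq_id].append(_AA20[rng.integers(20)])
            depth.append(None)
            consensus.append({})
    msa = {seq_id: "".join(columns[seq_id]) for seq_id in ids}
    truth = ConservedColumnSet(depth=tuple(depth), consensus=tuple(consensus))
    return msa, CladeMap(levels=levels), truth


def mutate_reference_paralogue(
    msa: Mapping[str, str],
    reference_id: str,
    truth: ConservedColumnSet,
    n_saavs: int = 4,
    seed: int = 0,
) -> tuple[ProteinRecord, tuple[tuple[int, str, str], ...]]:
    """Derive a paralogue from the reference row with SAAVs planted at
    conserved columns.

    Returns the mutated record and the planted list of
    (1-based alignment column, consensus residue, alternate residue) —
    the list a variant profile should recover exactly.
    """
    rng = np.random.default_rng(seed)
    ref_row = msa[reference_id]
    candidate_cols = [
        c
        for c in range(len(ref_row))
        if truth.depth[c] is not None and ref_row[c] not in "-."
    ]
    if len(candidate_cols) < n_saavs:
        raise ValidationError("not enough conserved columns to plant SAAVs")
    chosen = sorted(
        int(c) for c in rng.choice(len(candidate_cols), size=n_saavs, replace=False)
    )
    cols = [candidate_cols[i] for i in chosen]
    seq = [aa for aa in ref_row if aa not in "-."]
    res_index = {
        c: i for i, c in enumerate(k for k, aa in enumerate(ref_row) if aa not in "-.")
    }
    planted = []
    for c in cols:
        cons = truth.consensus[c][truth.depth[c]]
        others = [aa for aa in _AA20 if aa != cons]
        alt = others[rng.integers(len(others))]
        seq[res_index[c]] = alt
        planted.append((c + 1, cons, alt))
    record = ProteinRecord(
        id=f"{reference_id}_mut", sequence="".join(seq), description="planted paralogue"
    )
    return record, tuple(planted)
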