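"""Transcript coding-status assessment and gene-level coding/pseudogene calls.

A paralogue transcript is compared against the parent coding sequence (CDS)
by global nucleotide alignment with free end gaps. Lesions relative to the
parent are collected:

* ``premature_stop`` — a stop codon read in the parent frame upstream of the
  parent's stop. "In frame" means the codon is aligned gaplessly to a parent
  codon with the cumulative indel offset a multiple of 3, i.e. a ribosome
  translating the transcript in the parent's frame would actually read it.
* ``frameshift`` — an alignment indel whose length is not divisible by 3
  (in-frame indels change the protein but do not scramble it and are not
  lesions).
* ``truncated_5prime`` — the alignment starts a configurable number of
  codons (default 50, the size of a typical lost first coding exon) into
  the parent.
* ``fragment`` — aligned coverage below half the parent.

The gene verdict combines the lesion status with peptide evidence: a lesion
is disqualifying on its own; an intact transcript needs at least one unique
peptide to be called coding; an intact transcript with no distinguishing
evidence stays ambiguous unless a sibling paralogue (plus its common
variants) explains essentially all observations, in which case the intact
but unsupported copy is called a pseudogene by comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import ValidationError
from .tryptic import ParalogueEvidence
from ._align import aligned_pairs, nucleotide_aligner

__all__ = [
    "Lesion",
    "CodingStatus",
    "assess_transcript",
    "classify_gene",
    "STOP_CODONS",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_DNA = frozenset("ACGTN")

#: default number of missing leading codons that marks a 5' truncation
DEFAULT_TRUNCATION_CODONS = 50
#: default minimum aligned fraction of the parent below which the
#: transcript is just a fragment
DEFAULT_FRAGMENT_COVERAGE = 0.5
#: comparative pseudogene call: an intact paralogue with no unique peptides
#: is called a pseudogene when some sibling's variant-inclusive explained
#: fraction reaches this threshold
DEFAULT_COMPARATIVE_THRESHOLD = 0.99


@dataclass(frozen=True)
class Lesion:
    kind: str  # premature_stop | frameshift | truncated_5prime
    cds_position: int  # 1-based coordinate on the parent CDS
    detail: str = ""


@dataclass(frozen=True)
class CodingStatus:
    transcript_id: str
    status: str  # full_length_intact | premature_stop | frameshift | truncated_5prime | fragment
    lesions: tuple[Lesion, ...]
    predicted_protein_length: int
    coverage: float


def _validate_dna(seq: str, name: str) -> str:
    seq = seq.upper()
    for i, base in enumerate(seq, start=1):
        if base not in _DNA:
            raise ValidationError(f"{name}: non-DNA character {base!r} at position {i}")
    return seq


def _translated_length(seq: str) -> int:
    """Codons translated from the start of ``seq`` until the first stop."""
    n = 0
    for i in range(0, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            break
        n += 1
    return n


def assess_transcript(
    transcript_cds: str,
    parent_cds: str,
    transcript_id: str = "transcript",
    truncation_codons: int = DEFAULT_TRUNCATION_CODONS,
    fragment_coverage: float = DEFAULT_FRAGMENT_COVERAGE,
) -> CodingStatus:
    """Classify a transcript's coding ability relative to a parent CDS.

    The parent must be a whole CDS: length divisible by 3 and ending in a
    stop codon. All lesions found are listed; the status reports the most
    consequential one (fragment, then premature stop, then frameshift, then
    5' truncation), and ``full_length_intact`` exactly when the lesion list
    is empty.
    """
    transcript = _validate_dna(transcript_cds, f"transcript {transcript_id!r}")
    parent = _validate_dna(parent_cds, "parent CDS")
    if len(parent) % 3 != 0:
        raise ValidationError("parent CDS length must be divisible by 3")
    if parent[-3:] not in STOP_CODONS:
        raise ValidationError("parent CDS must end in a stop codon")

    aligner = nucleotide_aligner()
    alignment = aligner.align(parent, transcript)[0]
    pairs = aligned_pairs(alignment)

    aligned_idx = [(t, q) for t, q in pairs if t is not None and q is not None]
    if not aligned_idx:
        raise ValidationError("transcript does not align to parent at all")
    p0 = aligned_idx[0][0]
    coverage = len(aligned_idx) / len(parent)

    lesions: list[Lesion] = []

    # --- indels within the aligned core (end overhangs are not indels) -----
    i0 = next(i for i, (t, q) in enumerate(pairs) if t is not None and q is not None)
    i1 = len(pairs) - 1 - next(
        i for i, (t, q) in enumerate(reversed(pairs)) if t is not None and q is not None
    )
    core = pairs[i0 : i1 + 1]
    runs: list[tuple[str, int, int]] = []  # (kind, 0-based parent pos, length)
    run_kind: str | None = None
    run_len = 0
    run_at = 0
    offset = 0
    offset_at: dict[int, int] = {}  # parent index -> cumulative indel offset upstream
    last_t = core[0][0]
    for t, q in core:
        if t is not None and q is not None:
            if run_kind:
                runs.append((run_kind, run_at, run_len))
                run_kind, run_len = None, 0
            offset_at[t] = offset
            last_t = t
        elif t is None:  # insertion in transcript
            if run_kind != "ins":
                if run_kind:
                    runs.append((run_kind, run_at, run_len))
                run_kind, run_len, run_at = "ins", 0, last_t + 1
            run_len += 1
            offset += 1
        else:  # deletion in transcript
            if run_kind != "del":
                if run_kind:
                    runs.append((run_kind, run_at, run_len))
                run_kind, run_len, run_at = "del", 0, t
            run_len += 1
            offset -= 1
            last_t = t
    for kind, at, length in runs:
        if length % 3 != 0:
            lesions.append(
                Lesion(
                    "frameshift",
                    at + 1,
                    f"{kind} of {length} nt, {length} mod 3 = {length % 3}",
                )
            )

    # --- premature stops read in the parent frame --------------------------
    pair_of = {t: q for t, q in aligned_idx}
    parent_stop_codon = len(parent) - 3
    for p in range(0, parent_stop_codon, 3):
        if p < p0 or offset_at.get(p) is None:
            continue
        if offset_at[p] % 3 != 0:
            continue
        q = pair_of.get(p)
        if q is None:
            continue
        if pair_of.get(p + 1) != q + 1 or pair_of.get(p + 2) != q + 2:
            continue
        codon = transcript[q : q + 3]
        if codon in STOP_CODONS:
            lesions.append(Lesion("premature_stop", p + 1, f"stop codon {codon}"))

    # --- 5' truncation ------------------------------------------------------
    if p0 >= truncation_codons * 3:
        lesions.append(
            Lesion("truncated_5prime", 1, f"first {p0 // 3} parent codons missing")
        )

    lesions.sort(key=lambda l: (l.cds_position, l.kind))
    if coverage < fragment_coverage:
        status = "fragment"
    elif any(l.kind == "premature_stop" for l in lesions):
        status = "premature_stop"
    elif any(l.kind == "frameshift" for l in lesions):
        status = "frameshift"
    elif any(l.kind == "truncated_5prime" for l in lesions):
        status = "truncated_5prime"
    else:
        status = "full_length_intact"

    return CodingStatus(
        transcript_id=transcript_id,
        status=status,
        lesions=tuple(lesions),
        predicted_protein_length=_translated_length(transcript),
        coverage=coverage,
    )


def classify_gene(
    status: CodingStatus,
    attribution_entry: ParalogueEvidence,
    sibling_best_fraction: float | None = None,
    comparative_threshold: float = DEFAULT_COMPARATIVE_THRESHOLD,
) -> str:
    """Combine lesion status with peptide evidence into a gene verdict.

    Returns 'coding', 'pseudogene' or 'ambiguous'. ``sibling_best_fraction``
    is the best variant-inclusive explained-observation fraction among the
    *other* paralogues; when it reaches ``comparative_threshold``, an intact
    but evidence-free paralogue is called a pseudogene by comparison (all
    the observations are already accounted for by the sibling).
    """
    if status.transcript_id != attribution_entry.protein_id:
        raise ValidationError(
            f"id mismatch: status for {status.transcript_id!r} vs attribution for "
            f"{attribution_entry.protein_id!r}"
        )
    if status.status in ("premature_stop", "frameshift", "fragment"):
        return "pseudogene"
    n_unique = len(attribution_entry.unique)
    if status.status == "truncated_5prime":
        # attribution already maps against the (truncated) predicted protein,
        # so any unique peptide lies in the retained region
        return "coding" if n_unique >= 1 else "pseudogene"
    # full_length_intact
    if n_unique >= 1:
        return "coding"
    if sibling_best_fraction is not None and sibling_best_fraction >= comparative_threshold:
        return "pseudogene"
    return "ambiguous"
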