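"""Single-amino-acid-variant (SAAV) rescue of unmapped peptides, and allele
counting across haplotype panels.

A peptide that maps to no paralogue may still come from one of them if the
sample carries a common protein-level variant: the peptide then differs from
the reference protein at exactly one residue. Rescue searches every
equal-length window of a target protein for such single-substitution
explanations, re-checking trypticity and missed cleavages against the
*substituted* sequence (a substitution that creates or destroys a K/R can
make or break a tryptic boundary). Only single substitutions are considered
— no indels, no double variants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .io import PeptideObservation, ProteinRecord, ValidationError
from .tryptic import (
    AttributionReport,
    ParalogueEvidence,
    _boundaries_tryptic,
    count_missed_cleavages,
    map_peptide,
)

__all__ = [
    "VariantExplanation",
    "AlleleCount",
    "RescuePartition",
    "rescue_single_substitution",
    "summarize_haplotype_alleles",
    "explain_unmapped",
    "apply_rescue",
]

_GAPS = frozenset("-.")


@dataclass(frozen=True)
class VariantExplanation:
    """One single-substitution placement of a peptide on a protein."""

    peptide: str
    protein_id: str
    protein_position: int  # 1-based position of the substituted residue
    ref_residue: str
    obs_residue: str
    window_start: int  # 1-based start of the matched window
    supporting_exact_peptide: str | None = None


@dataclass(frozen=True)
class AlleleCount:
    """Residue histogram at one alignment column over a haplotype panel."""

    column: int  # 1-based
    counts: Mapping[str, int]
    gaps: int = 0

    @property
    def n_sequences(self) -> int:
        return sum(self.counts.values()) + self.gaps


def rescue_single_substitution(
    peptide: str,
    protein: ProteinRecord,
    max_missed: int = 2,
    proline_rule: bool = True,
) -> list[VariantExplanation]:
    """All single-substitution explanations of ``peptide`` on ``protein``.

    Precondition: the peptide has no exact fully tryptic match on the protein
    (exact matches are not variants — use :func:`map_peptide` first).
    Each returned window differs from the peptide at exactly one residue, and
    the peptide keeps tryptic boundaries and at most ``max_missed`` missed
    cleavages on the substituted protein sequence.
    """
    if not peptide:
        raise ValidationError("empty peptide")
    if map_peptide(peptide, [protein], max_missed=max_missed, proline_rule=proline_rule):
        raise ValidationError(
            f"peptide {peptide!r} has an exact tryptic match on {protein.id!r}; "
            "rescue applies only to unmapped peptides"
        )
    out: list[VariantExplanation] = []
    if "X" in peptide:
        return out
    seq = protein.sequence
    plen = len(peptide)
    for s in range(len(seq) - plen + 1):
        window = seq[s : s + plen]
        if "X" in window:
            continue
        diffs = [i for i in range(plen) if window[i] != peptide[i]]
        if len(diffs) != 1:
            continue
        i = diffs[0]
        substituted = seq[: s + i] + peptide[i] + seq[s + i + 1 :]
        nterm, cterm = _boundaries_tryptic(substituted, s, s + plen, proline_rule)
        if not (nterm and cterm):
            continue
        if count_missed_cleavages(peptide, proline_rule) > max_missed:
            continue
        out.append(
            VariantExplanation(
                peptide=peptide,
                protein_id=protein.id,
                protein_position=s + i + 1,
                ref_residue=window[i],
                obs_residue=peptide[i],
                window_start=s + 1,
            )
        )
    return out


def summarize_haplotype_alleles(
    panel: Sequence[str] | Mapping[str, str], column: int
) -> AlleleCount:
    """Residue histogram at a 1-based alignment ``column`` of a haplotype panel.

    Gaps are excluded from the histogram and reported separately.
    """
    rows = list(panel.values()) if isinstance(panel, Mapping) else list(panel)
    if not rows:
        raise ValidationError("empty panel")
    if len({len(r) for r in rows}) > 1:
        raise ValidationError("ragged panel: aligned sequences must have equal length")
    if not (1 <= column <= len(rows[0])):
        raise ValidationError(f"column {column} outside alignment of width {len(rows[0])}")
    counts: dict[str, int] = {}
    gaps = 0
    for row in rows:
        aa = row[column - 1]
        if aa in _GAPS:
            gaps += 1
        else:
            counts[aa] = counts.get(aa, 0) + 1
    return AlleleCount(column=column, counts=counts, gaps=gaps)


@dataclass(frozen=True)
class RescuePartition:
    """Unmapped peptides partitioned into variant-explained and unexplained."""

    target_id: str
    explained: Mapping[str, tuple[VariantExplanation, ...]]  # peptide -> windows
    unexplained: tuple[str, ...]
    explained_obs: int


def explain_unmapped(
    unmapped: Sequence[PeptideObservation],
    target: ProteinRecord,
    evidence: Sequence[PeptideObservation] = (),
    max_missed: int = 2,
    proline_rule: bool = True,
) -> RescuePartition:
    """Partition unmapped peptides by whether a single substitution on the
    target protein explains them.

    When multiple windows explain one peptide, all are reported but the
    peptide contributes its observations once. Each explanation is
    cross-checked against the evidence table for its exact-match counterpart
    (the unsubstituted window); a counterpart found there corroborates the
    variant, but its absence is not disqualifying.
    """
    evidence_set = {e.peptide for e in evidence}
    explained: dict[str, tuple[VariantExplanation, ...]] = {}
    unexplained: list[str] = []
    explained_obs = 0
    for obs in sorted(unmapped, key=lambda o: o.peptide):
        hits = rescue_single_substitution(
            obs.peptide, target, max_missed=max_missed, proline_rule=proline_rule
        )
        if not hits:
            unexplained.append(obs.peptide)
            continue
        corroborated = []
        for h in hits:
            counterpart = target.sequence[h.window_start - 1 : h.window_start - 1 + len(obs.peptide)]
            if counterpart in evidence_set:
                h = replace(h, supporting_exact_peptide=counterpart)
            corroborated.append(h)
        explained[obs.peptide] = tuple(corroborated)
        explained_obs += obs.n_obs
    return RescuePartition(
        target_id=target.id,
        explained=explained,
        unexplained=tuple(unexplained),
        explained_obs=explained_obs,
    )


def apply_rescue(report: AttributionReport, rescue: RescuePartition) -> AttributionReport:
    """Fold a rescue partition into the attribution report.

    Updates the target paralogue's variant fields so the report states the
    fraction of *all* observations attributable to that paralogue plus its
    variants; the variant-inclusive fraction can only grow relative to the
    exact-only one.
    """
    entries = []
    for e in report.paralogues:
        if e.protein_id == rescue.target_id:
            var_obs = rescue.explained_obs
            frac = (
                (e.captured_obs + var_obs) / report.total_obs if report.total_obs else 0.0
            )
            e = replace(
                e,
                variant_peptides=tuple(sorted(rescue.explained)),
                variant_obs=var_obs,
                variant_inclusive_fraction=frac,
            )
        entries.append(e)
    return AttributionReport(
        paralogues=tuple(entries),
        total_peptides=report.total_peptides,
        total_obs=report.total_obs,
        unmapped=report.unmapped,
    )
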