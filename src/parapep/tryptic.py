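"""In-silico tryptic digestion, peptide quality filters, peptide-to-paralogue
mapping and the unique-peptide / observation-weighted attribution.

Trypsin cleaves after lysine (K) or arginine (R). With the proline rule
enabled (the default, as in typical proteomics search settings), a K/R
immediately followed by proline is not cleaved. A peptide is *fully tryptic*
on a protein when its N-boundary is the protein start or follows a cleavage-
competent K/R, and its C-boundary is the protein end or itself a cleavage-
competent K/R. A *missed cleavage* is a cleavage-competent K/R internal to
the peptide (the C-terminal residue never counts).

Attribution then asks, for each paralogue, which filtered peptides it
captures (maps exactly to it), which of those are unique to it, and what
fraction of all peptide observations it explains. Unique peptides are the
decisive evidence: a peptide shared by several near-identical paralogues
cannot distinguish between them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import (
    PeptideObservation,
    ProteinRecord,
    ValidationError,
)

__all__ = [
    "PeptideMatch",
    "ParalogueEvidence",
    "AttributionReport",
    "count_missed_cleavages",
    "enumerate_tryptic_peptides",
    "filter_peptide_table",
    "map_peptide",
    "build_attribution",
]

_CLEAVERS = frozenset("KR")


def _internal_cleavage_sites(seq: str, proline_rule: bool = True) -> list[int]:
    """1-based positions i (1 <= i < len) where the bond after residue i is cut."""
    sites = []
    for i in range(1, len(seq)):
        if seq[i - 1] in _CLEAVERS and (not proline_rule or seq[i] != "P"):
            sites.append(i)
    return sites


def count_missed_cleavages(peptide: str, proline_rule: bool = True) -> int:
    """Number of cleavage-competent K/R internal to ``peptide``.

    The C-terminal residue never counts; with the proline rule, a K/R
    immediately followed by P within the peptide does not count either.
    """
    if not peptide:
        raise ValidationError("empty peptide")
    return len(_internal_cleavage_sites(peptide, proline_rule))


def enumerate_tryptic_peptides(
    protein: ProteinRecord | str,
    max_missed: int = 2,
    min_len: int = 7,
    max_len: int = 50,
    proline_rule: bool = True,
) -> set[tuple[str, int]]:
    """All fully tryptic peptides of ``protein`` as (peptide, 1-based start).

    Exactly the substrings whose N-boundary is the protein start or follows a
    cleavage site, whose C-boundary is the protein end or a cleavage site,
    with at most ``max_missed`` internal cleavage sites, within the length
    window. Fragments containing 'X' are dropped: an unknown residue cannot
    support an identification.
    """
    if max_missed < 0:
        raise ValidationError("max_missed must be >= 0")
    if not (1 <= min_len <= max_len):
        raise ValidationError("require 1 <= min_len <= max_len")
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    bounds = [0] + _internal_cleavage_sites(seq, proline_rule) + [len(seq)]
    out: set[tuple[str, int]] = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, len(bounds)):
            if j - i - 1 > max_missed:
                break
            pep = seq[bounds[i] : bounds[j]]
            if min_len <= len(pep) <= max_len and "X" not in pep:
                out.add((pep, bounds[i] + 1))
    return out


def filter_peptide_table(
    peptides: Sequence[PeptideObservation],
    min_obs: int = 2,
    max_missed: int = 2,
    proline_rule: bool = True,
) -> list[PeptideObservation]:
    """Apply the evidence-quality filters: drop low-observation peptides
    (singletons by default) and peptides with too many missed cleavages.

    The fully-tryptic requirement cannot be checked here — tryptic boundaries
    depend on the protein context — and is enforced at mapping time.
    """
    return [
        p
        for p in peptides
        if p.n_obs >= min_obs
        and count_missed_cleavages(p.peptide, proline_rule) <= max_missed
    ]


@dataclass(frozen=True)
class PeptideMatch:
    """A placement of a peptide on a protein (1-based inclusive coordinates)."""

    peptide: str
    protein_id: str
    start: int
    end: int
    missed_cleavages: int
    nterm_tryptic: bool
    cterm_tryptic: bool
    match_type: str = "exact"  # "exact" | "saav"
    substitution: tuple[int, str, str] | None = None  # (position, ref, obs)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.peptide):
            raise ValidationError("match coordinates inconsistent with peptide length")
        if (self.match_type == "saav") != (self.substitution is not None):
            raise ValidationError("substitution must be present iff match_type is 'saav'")


def _boundaries_tryptic(seq: str, start0: int, end0: int, proline_rule: bool) -> tuple[bool, bool]:
    """Tryptic-boundary flags for window seq[start0:end0] (0-based, half-open)."""
    nterm = start0 == 0 or (
        seq[start0 - 1] in _CLEAVERS and (not proline_rule or seq[start0] != "P")
    )
    cterm = end0 == len(seq) or (
        seq[end0 - 1] in _CLEAVERS and (not proline_rule or seq[end0] != "P")
    )
    return nterm, cterm


def map_peptide(
    peptide: str,
    proteins: Sequence[ProteinRecord],
    max_missed: int = 2,
    proline_rule: bool = True,
    il_equivalent: bool = False,
) -> list[PeptideMatch]:
    """Exact fully-tryptic placements of ``peptide`` on each protein.

    One match per occurrence where both boundaries are tryptic and the
    occurrence has at most ``max_missed`` missed cleavages; sorted by
    (protein id, start). An empty list means the peptide is unmapped.
    With ``il_equivalent`` isoleucine and leucine are treated as the same
    residue (they are isobaric and indistinguishable by most MS), which
    weakens paralogue discrimination and is off by default.
    """
    if not peptide:
        raise ValidationError("empty peptide")
    if "X" in peptide:
        return []
    canon = str.maketrans("I", "L") if il_equivalent else None
    key = peptide.translate(canon) if canon else peptide
    matches: list[PeptideMatch] = []
    for protein in sorted(proteins, key=lambda p: p.id):
        seq = protein.sequence
        hay = seq.translate(canon) if canon else seq
        plen = len(peptide)
        pos = hay.find(key)
        while pos != -1:
            window = seq[pos : pos + plen]
            if "X" not in window:
                nterm, cterm = _boundaries_tryptic(seq, pos, pos + plen, proline_rule)
                missed = count_missed_cleavages(window, proline_rule)
                if nterm and cterm and missed <= max_missed:
                    matches.append(
                        PeptideMatch(
                            peptide=peptide,
                            protein_id=protein.id,
                            start=pos + 1,
                            end=pos + plen,
                            missed_cleavages=missed,
                            nterm_tryptic=nterm,
                            cterm_tryptic=cterm,
                        )
                    )
            pos = hay.find(key, pos + 1)
    return matches


@dataclass(frozen=True)
class ParalogueEvidence:
    """Per-paralogue slice of an attribution report.

    ``captured`` are the filtered peptides with at least one exact fully
    tryptic match on this paralogue; ``unique`` those captured by no other
    paralogue. Observation totals sum ``n_obs`` over the respective sets, and
    ``explained_fraction`` divides captured observations by the grand total
    over all filtered peptides (mapped or not). The variant fields are zero
    until single-amino-acid-variant rescue has run for this paralogue.
    """

    protein_id: str
    captured: tuple[str, ...]
    unique: tuple[str, ...]
    captured_obs: int
    unique_obs: int
    explained_fraction: float
    variant_peptides: tuple[str, ...] = ()
    variant_obs: int = 0
    variant_inclusive_fraction: float = 0.0


@dataclass(frozen=True)
class AttributionReport:
    paralogues: tuple[ParalogueEvidence, ...]  # in ranking order
    total_peptides: int
    total_obs: int
    unmapped: tuple[tuple[str, int], ...]  # (peptide, n_obs), sorted

    @property
    def ranking(self) -> tuple[str, ...]:
        return tuple(e.protein_id for e in self.paralogues)

    def entry(self, protein_id: str) -> ParalogueEvidence:
        for e in self.paralogues:
            if e.protein_id == protein_id:
                return e
        raise KeyError(protein_id)

    @property
    def top(self) -> ParalogueEvidence:
        return self.paralogues[0]

    def to_dict(self) -> dict:
        return {
            "total_peptides": self.total_peptides,
            "total_observations": self.total_obs,
            "unmapped": [[p, n] for p, n in self.unmapped],
            "paralogues": [
                {
                    "protein_id": e.protein_id,
                    "captured": list(e.captured),
                    "unique": list(e.unique),
                    "captured_obs": e.captured_obs,
                    "unique_obs": e.unique_obs,
                    "explained_fraction": e.explained_fraction,
                    "variant_peptides": list(e.variant_peptides),
                    "variant_obs": e.variant_obs,
                    "variant_inclusive_fraction": e.variant_inclusive_fraction,
                }
                for e in self.paralogues
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "AttributionReport":
        return cls(
            paralogues=tuple(
                ParalogueEvidence(
                    protein_id=d["protein_id"],
                    captured=tuple(d["captured"]),
                    unique=tuple(d["unique"]),
                    captured_obs=int(d["captured_obs"]),
                    unique_obs=int(d["unique_obs"]),
                    explained_fraction=float(d["explained_fraction"]),
                    variant_peptides=tuple(d["variant_peptides"]),
                    variant_obs=int(d["variant_obs"]),
                    variant_inclusive_fraction=float(d["variant_inclusive_fraction"]),
                )
                for d in payload["paralogues"]
            ),
            total_peptides=int(payload["total_peptides"]),
            total_obs=int(payload["total_observations"]),
            unmapped=tuple((p, int(n)) for p, n in payload["unmapped"]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.paralogues) + 1),
                "protein_id": [e.protein_id for e in self.paralogues],
                "n_captured": [len(e.captured) for e in self.paralogues],
                "n_unique": [len(e.unique) for e in self.paralogues],
                "captured_obs": [e.captured_obs for e in self.paralogues],
                "unique_obs": [e.unique_obs for e in self.paralogues],
                "explained_fraction": [e.explained_fraction for e in self.paralogues],
                "variant_obs": [e.variant_obs for e in self.paralogues],
                "variant_inclusive_fraction": [
                    e.variant_inclusive_fraction for e in self.paralogues
                ],
            }
        )


def build_attribution(
    peptides: Sequence[PeptideObservation],
    proteins: Sequence[ProteinRecord],
    max_missed: int = 2,
    proline_rule: bool = True,
    il_equivalent: bool = False,
) -> AttributionReport:
    """Capture / unique / observation-weighted attribution over a paralogue panel.

    A peptide occurring several times within one protein counts once toward
    that protein's capture set. Ranking is by descending explained-observation
    fraction, ties broken by larger unique-observation total, then
    lexicographic protein id; the result is invariant to input order.
    """
    if not proteins:
        raise ValidationError("empty protein collection")
    obs_of = {p.peptide: p.n_obs for p in peptides}
    total_obs = sum(obs_of.values())
    captured: dict[str, set[str]] = {p.id: set() for p in proteins}
    owners: dict[str, set[str]] = {}
    for pep in sorted(obs_of):
        for m in map_peptide(
            pep, proteins, max_missed=max_missed, proline_rule=proline_rule,
            il_equivalent=il_equivalent,
        ):
            captured[m.protein_id].add(pep)
            owners.setdefault(pep, set()).add(m.protein_id)
    unmapped = tuple((p, obs_of[p]) for p in sorted(obs_of) if p not in owners)
    entries = []
    for pid in sorted(captured):
        cap = tuple(sorted(captured[pid]))
        uniq = tuple(p for p in cap if owners[p] == {pid})
        cap_obs = sum(obs_of[p] for p in cap)
        uniq_obs = sum(obs_of[p] for p in uniq)
        frac = cap_obs / total_obs if total_obs else 0.0
        entries.append(
            ParalogueEvidence(
                protein_id=pid,
                captured=cap,
                unique=uniq,
                captured_obs=cap_obs,
                unique_obs=uniq_obs,
                explained_fraction=frac,
                variant_inclusive_fraction=frac,
            )
        )
    entries.sort(key=lambda e: (-e.explained_fraction, -e.unique_obs, e.protein_id))
    return AttributionReport(
        paralogues=tuple(entries),
        total_peptides=len(obs_of),
        total_obs=total_obs,
        unmapped=unmapped,
    )
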