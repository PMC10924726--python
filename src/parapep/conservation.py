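"""Cross-species conservation profiling of paralogue variants.

Given an orthologue multiple alignment whose rows are labelled with nested
clade levels (primates ⊂ mammals ⊂ tetrapods ⊂ vertebrates), each column is
scored for the deepest clade at which it is conserved. A paralogue is then
profiled against the alignment's reference row: every single-amino-acid
difference falling in a conserved column is recorded as a SAAV with the
clade depth of that column, classified as conservative or radical by a fixed
physicochemical exchange grouping; deletions and insertions relative to the
reference are listed as well. A paralogue that accumulates radical changes
at deeply conserved positions has drifted from the functional sequence —
the signature of a pseudogene — while the copy that preserves them is the
best candidate for producing the observed protein.

Variant names (e.g. G343S) use the paralogue's own 1-based residue
coordinates, not alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import CLADE_LEVELS, CladeMap, ProteinRecord, ValidationError
from ._align import aligned_pairs, protein_aligner

__all__ = [
    "EXCHANGE_GROUPS",
    "SAAV",
    "ConservedColumnSet",
    "ParalogVariantProfile",
    "SharedVariant",
    "qc_orthologues",
    "conserved_columns",
    "classify_substitution",
    "profile_paralogue_variants",
    "shared_derived_variants",
]

_GAPS = frozenset("-.")

#: Physicochemical exchange groups: substitutions within a group are
#: conservative, across groups non-conservative. A fixed published-style
#: grouping, pinned here as configuration.
EXCHANGE_GROUPS = ("AGPST", "ILMV", "DENQ", "KRH", "FWY", "C")
_GROUP_OF = {aa: grp for grp in EXCHANGE_GROUPS for aa in grp}


class AlignmentError(RuntimeError):
    """A required pairwise alignment could not be produced."""


def classify_substitution(ref: str, alt: str) -> str:
    """'conservative' if ref and alt share an exchange group, else
    'non_conservative'. Symmetric and deterministic."""
    if ref == alt:
        raise ValidationError("ref and alt residues must differ")
    for aa in (ref, alt):
        if aa not in _GROUP_OF:
            raise ValidationError(f"non-standard residue {aa!r}")
    return "conservative" if _GROUP_OF[ref] == _GROUP_OF[alt] else "non_conservative"


@dataclass(frozen=True)
class ConservedColumnSet:
    """Per-column conservation depth and per-level consensus residues.

    ``depth[c]`` is the deepest clade level at which column ``c`` (0-based)
    is conserved, or None; ``consensus[c]`` maps each satisfied level to its
    modal residue. Conservation is monotone by construction: a column
    conserved across vertebrates is conserved across tetrapods, mammals and
    primates.
    """

    depth: tuple[str | None, ...]
    consensus: tuple[Mapping[str, str], ...]

    @property
    def n_columns(self) -> int:
        return len(self.depth)

    def is_conserved_at(self, column: int, level: str) -> bool:
        """0-based ``column``; True if conserved at ``level`` (or deeper)."""
        d = self.depth[column]
        return d is not None and CLADE_LEVELS.index(d) >= CLADE_LEVELS.index(level)

    def consensus_at(self, column: int) -> str | None:
        """Consensus residue at the deepest conserved level, or None."""
        d = self.depth[column]
        return self.consensus[column][d] if d is not None else None


def conserved_columns(
    msa: Mapping[str, str],
    clades: CladeMap,
    min_fraction: float = 1.0,
    max_gap_fraction: float = 0.0,
) -> ConservedColumnSet:
    """Score every alignment column for its deepest conserved clade level.

    A column is conserved at level L when, among rows whose species fall
    inside clade L, the gap fraction is within tolerance and the modal
    residue's frequency (over non-gap rows) reaches ``min_fraction``. The
    defaults (1.0 / 0.0) demand strict identity with no gaps. Monotonicity is
    enforced: the recorded depth is the deepest level of the unbroken chain
    starting at the shallowest clade.
    """
    if not msa:
        raise ValidationError("empty alignment")
    width = {len(s) for s in msa.values()}
    if len(width) > 1:
        raise ValidationError("alignment rows have unequal lengths")
    n_cols = width.pop()
    members = {level: [msa[i] for i in clades.members_at(level) if i in msa] for level in CLADE_LEVELS}
    for seq_id in msa:
        clades.level_of(seq_id)  # raises if unlabelled
    depth: list[str | None] = []
    consensus: list[dict[str, str]] = []
    for c in range(n_cols):
        deepest: str | None = None
        cons: dict[str, str] = {}
        for level in CLADE_LEVELS:
            rows = members[level]
            if not rows:
                break
            residues = [r[c] for r in rows]
            gaps = sum(1 for aa in residues if aa in _GAPS)
            if gaps / len(residues) > max_gap_fraction:
                break
            non_gap = [aa for aa in residues if aa not in _GAPS]
            if not non_gap:
                break
            modal = max(sorted(set(non_gap)), key=non_gap.count)
            if non_gap.count(modal) / len(residues) < min_fraction:
                break
            deepest = level
            cons[level] = modal
        depth.append(deepest)
        consensus.append(cons)
    return ConservedColumnSet(depth=tuple(depth), consensus=tuple(consensus))


def qc_orthologues(
    msa: Mapping[str, str],
    reference_id: str,
    max_indel: int = 7,
) -> list[str]:
    """Orthologue inclusion rule: keep candidates whose pairwise projection
    against the reference row has no insertion or deletion run longer than
    ``max_indel`` columns, and which retain the reference's first and last
    aligned residues (the ancestral N- and C-termini).

    Returns the retained ids (the reference is always retained).
    """
    if reference_id not in msa:
        raise ValidationError(f"reference {reference_id!r} not in alignment")
    widths = {len(s) for s in msa.values()}
    if len(widths) > 1:
        raise ValidationError("unaligned input: rows have unequal lengths")
    ref = msa[reference_id]
    ref_res_cols = [c for c, aa in enumerate(ref) if aa not in _GAPS]
    if not ref_res_cols:
        raise ValidationError("reference row is all gaps")
    first_c, last_c = ref_res_cols[0], ref_res_cols[-1]
    retained = [reference_id]
    for seq_id, row in msa.items():
        if seq_id == reference_id:
            continue
        if row[first_c] in _GAPS or row[last_c] in _GAPS:
            continue
        ok = True
        run_kind: str | None = None  # "del" (gap in candidate) / "ins" (gap in ref)
        run_len = 0
        for c in range(len(ref)):
            r_gap, q_gap = ref[c] in _GAPS, row[c] in _GAPS
            if r_gap and q_gap:
                continue
            kind = "del" if q_gap else ("ins" if r_gap else None)
            if kind == run_kind and kind is not None:
                run_len += 1
            else:
                run_kind, run_len = kind, 1 if kind else 0
            if kind and run_len > max_indel:
                ok = False
                break
        if ok:
            retained.append(seq_id)
    return retained


@dataclass(frozen=True)
class SAAV:
    """One single-amino-acid difference at a conserved alignment column."""

    column: int  # 1-based alignment column
    ref_residue: str  # consensus at the deepest conserved level
    alt_residue: str
    clade_depth: str
    conservative: bool
    paralogue_position: int  # 1-based coordinate in the paralogue itself

    @property
    def name(self) -> str:
        """Field-style variant name, e.g. 'G343S'."""
        return f"{self.ref_residue}{self.paralogue_position}{self.alt_residue}"


@dataclass(frozen=True)
class ParalogVariantProfile:
    paralogue_id: str
    saavs: tuple[SAAV, ...]
    deletions: tuple[tuple[int, int, int], ...]  # (col_start, col_end, length)
    insertions: tuple[tuple[int, int], ...]  # (after column, length)

    def saav_total_at(self, level: str) -> int:
        """SAAVs falling in columns conserved at ``level`` or deeper."""
        cutoff = CLADE_LEVELS.index(level)
        return sum(1 for s in self.saavs if CLADE_LEVELS.index(s.clade_depth) >= cutoff)

    @property
    def saav_totals(self) -> dict[str, int]:
        return {level: self.saav_total_at(level) for level in CLADE_LEVELS}


def profile_paralogue_variants(
    paralogue: ProteinRecord,
    msa: Mapping[str, str],
    reference_id: str,
    conserved: ConservedColumnSet,
) -> ParalogVariantProfile:
    """Profile a paralogue's differences against the conserved columns of an
    orthologue alignment.

    The paralogue is globally aligned (BLOSUM62, affine gaps) to the
    ungapped reference row; reference residues are then mapped back to
    alignment columns. A SAAV is recorded wherever the paralogue differs
    from the consensus of a conserved column; deletions and insertions are
    recorded relative to the reference regardless of conservation.
    """
    if reference_id not in msa:
        raise ValidationError(f"reference {reference_id!r} not in alignment")
    ref_row = msa[reference_id]
    if len(ref_row) != conserved.n_columns:
        raise ValidationError("conserved column set does not match alignment width")
    ref_seq = "".join(aa for aa in ref_row if aa not in _GAPS)
    res_to_col = [c for c, aa in enumerate(ref_row) if aa not in _GAPS]

    aligner = protein_aligner()
    alignments = aligner.align(ref_seq, paralogue.sequence)
    if len(alignments) == 0 or alignments.score <= 0:
        raise AlignmentError(
            f"no positive-scoring global alignment of {paralogue.id!r} to reference"
        )
    pairs = aligned_pairs(alignments[0])

    saavs: list[SAAV] = []
    deletions: list[tuple[int, int, int]] = []
    insertions: list[tuple[int, int]] = []
    del_run: list[int] = []  # reference residue indices currently deleted
    ins_run = 0
    last_ref_idx = -1
    for t, q in pairs:
        if t is not None and q is not None:
            if del_run:
                cols = [res_to_col[i] for i in del_run]
                deletions.append((cols[0] + 1, cols[-1] + 1, len(del_run)))
                del_run = []
            if ins_run:
                after = res_to_col[last_ref_idx] + 1 if last_ref_idx >= 0 else 0
                insertions.append((after, ins_run))
                ins_run = 0
            last_ref_idx = t
            col = res_to_col[t]
            cons = conserved.consensus_at(col)
            alt = paralogue.sequence[q]
            if cons is not None and alt != cons and alt in _GROUP_OF:
                depth = conserved.depth[col]
                saavs.append(
                    SAAV(
                        column=col + 1,
                        ref_residue=cons,
                        alt_residue=alt,
                        clade_depth=depth,
                        conservative=classify_substitution(cons, alt) == "conservative",
                        paralogue_position=q + 1,
                    )
                )
        elif t is not None:  # reference residue absent from paralogue
            del_run.append(t)
        else:  # paralogue residue absent from reference
            ins_run += 1
    if del_run:
        cols = [res_to_col[i] for i in del_run]
        deletions.append((cols[0] + 1, cols[-1] + 1, len(del_run)))
    if ins_run:
        after = res_to_col[last_ref_idx] + 1 if last_ref_idx >= 0 else 0
        insertions.append((after, ins_run))
    return ParalogVariantProfile(
        paralogue_id=paralogue.id,
        saavs=tuple(saavs),
        deletions=tuple(deletions),
        insertions=tuple(insertions),
    )


@dataclass(frozen=True)
class SharedVariant:
    column: int
    ref_residue: str
    alt_residues: tuple[str, ...]
    paralogue_ids: tuple[str, ...]

    @property
    def name(self) -> str:
        return f"{self.ref_residue}{self.column}{'/'.join(self.alt_residues)}"


def shared_derived_variants(
    profiles: Sequence[ParalogVariantProfile],
    min_share: int = 2,
    pool_alternates: bool = False,
) -> list[SharedVariant]:
    """Variants present in at least ``min_share`` profiles.

    By default a variant is (column, alt residue); with ``pool_alternates``
    different alternate residues at the same column are pooled into one
    entry (reported like 'Y141D/E'), the way a column recurrently hit in
    several paralogues is counted as a single shared change. A block of
    shared derived variants across paralogues is the fingerprint of descent
    from a common, already-diverged ancestor. Sorted by column.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles")
    groups: dict[tuple, dict] = {}
    for prof in profiles:
        for s in prof.saavs:
            key = (s.column,) if pool_alternates else (s.column, s.alt_residue)
            g = groups.setdefault(key, {"ref": s.ref_residue, "alts": set(), "ids": set()})
            g["alts"].add(s.alt_residue)
            g["ids"].add(prof.paralogue_id)
    out = [
        SharedVariant(
            column=key[0],
            ref_residue=g["ref"],
            alt_residues=tuple(sorted(g["alts"])),
            paralogue_ids=tuple(sorted(g["ids"])),
        )
        for key, g in groups.items()
        if len(g["ids"]) >= min_share
    ]
    out.sort(key=lambda v: (v.column, v.alt_residues))
    return out
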