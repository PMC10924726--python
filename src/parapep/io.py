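"""Readers, writers and core record types for the paralogue-arbitration pipeline.

The pipeline works at the peptide-evidence level: protein sequences come in
as FASTA, peptide evidence as a tab-separated table of
``peptide\tn_obs[\tsamples]`` rows (one row per detected peptide with its
observation count, PeptideAtlas style), orthologue panels as aligned FASTA
with a two-column clade map, and attribution results go out as a
schema-versioned JSON report plus a flat per-paralogue TSV.

All residue coordinates everywhere in the package are 1-based and inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ValidationError",
    "STANDARD_RESIDUES",
    "PROTEIN_ALPHABET",
    "CLADE_LEVELS",
    "ProteinRecord",
    "PeptideObservation",
    "CladeMap",
    "read_protein_fasta",
    "write_protein_fasta",
    "read_alignment_fasta",
    "read_peptide_table",
    "write_peptide_table",
    "read_clade_map",
    "write_clade_map",
    "write_attribution_report",
    "read_attribution_report",
]


class FormatError(ValueError):
    """A file does not conform to its expected dialect."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


#: The 20 standard amino acids.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Residues allowed in a ProteinRecord; 'X' marks an unknown residue and
#: never matches anything downstream.
PROTEIN_ALPHABET = STANDARD_RESIDUES | {"X"}

#: Nested clade levels, shallowest first: every primate is a mammal, every
#: mammal a tetrapod, every tetrapod a vertebrate.
CLADE_LEVELS = ("primates", "mammals", "tetrapods", "vertebrates")

_SOURCES = ("GRCh38", "CHM13", "UniProt", "RefSeq", "GenBank", "synthetic")


@dataclass(frozen=True)
class ProteinRecord:
    """One paralogue's (predicted) protein sequence with provenance."""

    id: str
    sequence: str
    description: str = ""
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in PROTEIN_ALPHABET:
                raise ValidationError(
                    f"protein {self.id!r}: illegal residue {aa!r} at position {pos}"
                )
        if self.source not in _SOURCES:
            raise ValidationError(
                f"protein {self.id!r}: unknown source {self.source!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideObservation:
    """One detected peptide with its observation count.

    ``n_obs`` is the number of distinct detections across experiments
    (a rough expression proxy), not a spectral count within one run.
    """

    peptide: str
    n_obs: int
    samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.peptide) < 1:
            raise ValidationError("peptide must be non-empty")
        if self.n_obs < 0:
            raise ValidationError(
                f"peptide {self.peptide!r}: negative n_obs {self.n_obs}"
            )


@dataclass(frozen=True)
class CladeMap:
    """Maps each orthologue sequence id to the clade level of its species."""

    levels: Mapping[str, str]

    def __post_init__(self) -> None:
        for seq_id, level in self.levels.items():
            if level not in CLADE_LEVELS:
                raise ValidationError(
                    f"sequence {seq_id!r}: unknown clade level {level!r}"
                )

    def level_of(self, seq_id: str) -> str:
        try:
            return self.levels[seq_id]
        except KeyError:
            raise ValidationError(f"no clade level for sequence {seq_id!r}") from None

    def level_index(self, seq_id: str) -> int:
        return CLADE_LEVELS.index(self.level_of(seq_id))

    def members_at(self, level: str) -> list[str]:
        """Ids whose species fall inside the clade at ``level``."""
        cutoff = CLADE_LEVELS.index(level)
        return [s for s in self.levels if CLADE_LEVELS.index(self.levels[s]) <= cutoff]


def _check_duplicate_ids(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id {i!r}")
        seen.add(i)


def read_protein_fasta(path: str | Path, source: str = "synthetic") -> list[ProteinRecord]:
    """Read a (multi-record) protein FASTA.

    Sequences are uppercased and a single terminal ``*`` (stop) is stripped.
    Duplicate ids and illegal residues are rejected.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.read(1)
        while first.isspace():
            first = handle.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: line 1: FASTA must start with '>'")
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        records.append(
            ProteinRecord(id=rec.id, sequence=seq, description=rec.description, source=source)
        )
    _check_duplicate_ids((r.id for r in records), "protein")
    return records


def write_protein_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    _check_duplicate_ids((r.id for r in records), "protein")
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA (rows may contain gap characters ``-``/``.``).

    Returns an id -> row mapping preserving file order; all rows must have
    equal length.
    """
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValidationError(f"duplicate alignment row id {rec.id!r}")
        rows[rec.id] = str(rec.seq).upper()
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValidationError(f"{path}: alignment rows have unequal lengths {sorted(lengths)}")
    return rows


def read_peptide_table(path: str | Path) -> list[PeptideObservation]:
    """Read a peptide evidence TSV with header ``peptide\tn_obs[\tsamples]``.

    Rows with identical peptide strings are aggregated by summing their
    observation counts (and unioning sample tags), so exports that list one
    row per experiment are handled the same way as one-row-per-peptide
    exports. Aggregation is order-independent.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"peptide": str}, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected a header line") from None
    for col in ("peptide", "n_obs"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    merged: dict[str, int] = {}
    samples: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        pep = str(row["peptide"]).strip().upper()
        n = int(row["n_obs"])
        if n < 0:
            raise ValidationError(f"{path}: peptide {pep!r} has negative n_obs {n}")
        merged[pep] = merged.get(pep, 0) + n
        if "samples" in df.columns and not pd.isna(row.get("samples")):
            tags = [t for t in str(row["samples"]).split(";") if t]
            samples.setdefault(pep, []).extend(tags)
    return [
        PeptideObservation(
            peptide=pep,
            n_obs=merged[pep],
            samples=tuple(sorted(set(samples.get(pep, ())))),
        )
        for pep in sorted(merged)
    ]


def write_peptide_table(observations: Sequence[PeptideObservation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "peptide": [o.peptide for o in observations],
            "n_obs": [o.n_obs for o in observations],
            "samples": [";".join(o.samples) for o in observations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_clade_map(path: str | Path) -> CladeMap:
    """Read a two-column TSV (sequence id, clade level)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "level"], dtype=str)
    return CladeMap(levels=dict(zip(df["id"], df["level"])))


def write_clade_map(clades: CladeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, level in clades.levels.items():
            fh.write(f"{seq_id}\t{level}\n")


# -- attribution report serialisation ---------------------------------------
# The report types live in parapep.tryptic; imported lazily to keep this
# module at the bottom of the dependency stack.

REPORT_SCHEMA = "parapep-attribution/1"


def write_attribution_report(report, path: str | Path, tsv_path: str | Path | None = None) -> None:
    """Write an AttributionReport as schema-versioned JSON plus a flat TSV.

    ``tsv_path`` defaults to the JSON path with a ``.tsv`` suffix. Re-reading
    the JSON with :func:`read_attribution_report` reproduces the report
    exactly.
    """
    path = Path(path)
    payload = {"schema": REPORT_SCHEMA, **report.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")
    if tsv_path is None:
        tsv_path = path.with_suffix(".tsv")
    report.to_frame().to_csv(tsv_path, sep="\t", index=False)


def read_attribution_report(path: str | Path):
    from .tryptic import AttributionReport

    with open(path) as fh:
        payload = json.load(fh)
    schema = payload.pop("schema", None)
    if schema != REPORT_SCHEMA:
        raise FormatError(f"{path}: unsupported report schema {schema!r}")
    return AttributionReport.from_dict(payload)
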