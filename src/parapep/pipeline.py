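"""End-to-end orchestration: filter -> map -> attribute -> rescue ->
(optional) conservation profile -> (optional) coding status -> verdicts.

The pipeline decides which member of a paralogue family the peptide
evidence supports: it filters the evidence table, maps peptides onto every
paralogue, attributes observations, rescues unmapped peptides as single
amino acid variants of the top-ranked paralogue, and — when orthologue
alignments and CDS sequences are supplied — profiles conservation damage
and classifies each gene as coding, pseudogene or ambiguous.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .coding import (
    DEFAULT_COMPARATIVE_THRESHOLD,
    DEFAULT_FRAGMENT_COVERAGE,
    DEFAULT_TRUNCATION_CODONS,
    CodingStatus,
    assess_transcript,
    classify_gene,
)
from .conservation import (
    AlignmentError,
    ConservedColumnSet,
    ParalogVariantProfile,
    conserved_columns,
    profile_paralogue_variants,
)
from .io import (
    ProteinRecord,
    read_alignment_fasta,
    read_clade_map,
    read_peptide_table,
    read_protein_fasta,
    write_attribution_report,
)
from .tryptic import AttributionReport, build_attribution, filter_peptide_table
from .variants import RescuePartition, apply_rescue, explain_unmapped

logger = logging.getLogger("parapep")

__all__ = ["PipelineConfig", "PipelineResult", "run_attribution_pipeline"]


@dataclass
class PipelineConfig:
    proteins_path: str
    peptides_path: str
    out_dir: str
    msa_path: str | None = None
    clade_map_path: str | None = None
    msa_reference: str | None = None
    cds_path: str | None = None
    parent_cds_id: str | None = None
    min_obs: int = 2
    max_missed: int = 2
    proline_rule: bool = True
    il_equivalent: bool = False
    rescue: bool = True
    conservation_min_fraction: float = 1.0
    comparative_threshold: float = DEFAULT_COMPARATIVE_THRESHOLD
    truncation_codons: int = DEFAULT_TRUNCATION_CODONS
    fragment_coverage: float = DEFAULT_FRAGMENT_COVERAGE

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    report: AttributionReport
    rescue: RescuePartition | None
    profiles: dict[str, ParalogVariantProfile]
    conserved: ConservedColumnSet | None
    statuses: dict[str, CodingStatus]
    verdicts: dict[str, str]
    manifest: dict


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_attribution_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run(config: PipelineConfig, out_dir: Path) -> PipelineResult:
    proteins = read_protein_fasta(config.proteins_path)
    raw = read_peptide_table(config.peptides_path)
    logger.info(
        "loaded %d paralogues, %d raw peptides (%d observations)",
        len(proteins),
        len(raw),
        sum(p.n_obs for p in raw),
    )

    filtered = filter_peptide_table(
        raw, min_obs=config.min_obs, max_missed=config.max_missed,
        proline_rule=config.proline_rule,
    )
    logger.info(
        "filters kept %d peptides (%d observations)",
        len(filtered),
        sum(p.n_obs for p in filtered),
    )
    if not filtered:
        logger.warning("empty filtered peptide set: report will be zeroed")

    report = build_attribution(
        filtered,
        proteins,
        max_missed=config.max_missed,
        proline_rule=config.proline_rule,
        il_equivalent=config.il_equivalent,
    )
    for e in report.paralogues:
        logger.info(
            "%s: %d captured (%d obs), %d unique (%d obs), explains %.4f",
            e.protein_id, len(e.captured), e.captured_obs, len(e.unique),
            e.unique_obs, e.explained_fraction,
        )

    rescue = None
    if config.rescue and filtered:
        target = next(p for p in proteins if p.id == report.top.protein_id)
        obs_of = {p.peptide: p for p in filtered}
        unmapped_obs = [obs_of[pep] for pep, _ in report.unmapped]
        rescue = explain_unmapped(
            unmapped_obs, target, evidence=filtered,
            max_missed=config.max_missed, proline_rule=config.proline_rule,
        )
        report = apply_rescue(report, rescue)
        logger.info(
            "rescue on %s: %d of %d unmapped peptides variant-explained "
            "(variant-inclusive fraction %.4f)",
            target.id, len(rescue.explained), len(unmapped_obs),
            report.entry(target.id).variant_inclusive_fraction,
        )

    profiles: dict[str, ParalogVariantProfile] = {}
    conserved = None
    if config.msa_path and config.clade_map_path:
        msa = read_alignment_fasta(config.msa_path)
        clades = read_clade_map(config.clade_map_path)
        reference = config.msa_reference or next(iter(msa))
        conserved = conserved_columns(
            msa, clades, min_fraction=config.conservation_min_fraction
        )
        for protein in proteins:
            try:
                profiles[protein.id] = profile_paralogue_variants(
                    protein, msa, reference, conserved
                )
            except AlignmentError:
                logger.warning(
                    "%s does not align to the orthologue reference; profile skipped",
                    protein.id,
                )
                continue
            logger.info(
                "%s: %d SAAVs at conserved columns, %d deletions",
                protein.id,
                len(profiles[protein.id].saavs),
                len(profiles[protein.id].deletions),
            )
    elif config.msa_path or config.clade_map_path:
        logger.info("conservation stage skipped: need both --msa and --clade-map")

    statuses: dict[str, CodingStatus] = {}
    verdicts: dict[str, str] = {}
    if config.cds_path:
        cds = {
            r.id: str(r.seq).upper()
            for r in SeqIO.parse(str(config.cds_path), "fasta")
        }
        parent_id = config.parent_cds_id or report.top.protein_id
        if parent_id not in cds:
            logger.info("coding-status stage skipped: parent CDS %r missing", parent_id)
        else:
            parent = cds[parent_id]
            best = {
                e.protein_id: e.variant_inclusive_fraction for e in report.paralogues
            }
            for cds_id in sorted(cds):
                statuses[cds_id] = assess_transcript(
                    cds[cds_id],
                    parent,
                    transcript_id=cds_id,
                    truncation_codons=config.truncation_codons,
                    fragment_coverage=config.fragment_coverage,
                )
                try:
                    entry = report.entry(cds_id)
                except KeyError:
                    logger.info("no attribution entry for %s; verdict skipped", cds_id)
                    continue
                sibling_best = max(
                    (f for pid, f in best.items() if pid != cds_id), default=None
                )
                verdicts[cds_id] = classify_gene(
                    statuses[cds_id],
                    entry,
                    sibling_best_fraction=sibling_best,
                    comparative_threshold=config.comparative_threshold,
                )
                logger.info(
                    "%s: %s -> %s", cds_id, statuses[cds_id].status, verdicts[cds_id]
                )
    elif config.msa_path is None and config.cds_path is None:
        logger.info("conservation and coding-status stages skipped (no inputs)")

    # --- artifacts ---------------------------------------------------------
    write_attribution_report(report, out_dir / "report.json", out_dir / "report.tsv")
    if verdicts:
        rows = [
            {
                "gene_id": g,
                "status": statuses[g].status,
                "lesions": ";".join(
                    f"{l.kind}@{l.cds_position}" for l in statuses[g].lesions
                ),
                "predicted": verdicts[g],
            }
            for g in sorted(verdicts)
        ]
        pd.DataFrame(rows).to_csv(out_dir / "verdicts.tsv", sep="\t", index=False)
    manifest = {
        "package": "parapep",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        report=report,
        rescue=rescue,
        profiles=profiles,
        conserved=conserved,
        statuses=statuses,
        verdicts=verdicts,
        manifest=manifest,
    )
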