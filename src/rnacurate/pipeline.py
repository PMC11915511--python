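"""End-to-end curation pipeline and its output writers.

Stage order is fixed — metadata filter (entry level), structure parsing +
chain filter (instance level), SI-based redundancy removal, Rfam family
annotation/dedup — so that the expensive all-vs-all alignment only sees
chains that already passed the cheap filters.  Every stage reports input,
retained and removed counts; the run is fully deterministic, so identical
inputs produce byte-identical TSV/FASTA/JSON outputs.

The first two stages count different units (PDB entries, then polymer
chains); each stage therefore carries a ``unit`` field and count chaining
holds between consecutive stages of the same unit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import Catalog, load_catalog
from .dataset import DATASET_COLUMNS, DatasetEntry
from .metadata_filter import MetadataFilterConfig, filter_metadata
from .redundancy import LabelAttrs, RedundancyConfig, Removal, select_representatives
from .rfam_annotation import AnnotationConfig, annotate_and_dedup, best_hit_per_query, parse_tblout
from .seq_identity import AlignmentParams, build_si_matrix
from .structure_parser import ChainFilterConfig, ChainRecord, filter_chains, parse_structure

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "Stage",
    "StageReport",
    "build_dataset",
    "write_dataset_tsv",
    "read_dataset_tsv",
    "write_fasta",
    "write_report_json",
]


@dataclass(frozen=True)
class Stage:
    name: str
    unit: str  # "entries" or "chains"
    input_count: int
    retained_count: int
    removed_count: int
    elapsed_seconds: float = 0.0

    def __post_init__(self) -> None:
        if self.retained_count + self.removed_count != self.input_count:
            raise ValueError(f"stage {self.name}: counts do not partition the input")


@dataclass(frozen=True)
class StageReport:
    """Ordered per-stage retention accounting for one pipeline run."""

    stages: tuple[Stage, ...]
    redundancy_removals: tuple[Removal, ...] = ()
    removal_reasons: tuple[tuple[str, str, str], ...] = ()  # (stage, id, reason)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            if prev.unit == cur.unit and cur.input_count != prev.retained_count:
                raise ValueError(
                    f"stage {cur.name}: input {cur.input_count} != previous retained "
                    f"{prev.retained_count}"
                )

    def to_json_dict(self) -> dict:
        """Deterministic machine-readable form (no timings; those go to the log)."""
        return {
            "stages": [
                {
                    "name": s.name,
                    "unit": s.unit,
                    "input": s.input_count,
                    "retained": s.retained_count,
                    "removed": s.removed_count,
                }
                for s in self.stages
            ],
            "redundancy_removals": [
                {"removed": r.removed, "kept": r.kept, "identity": round(r.identity, 6)}
                for r in self.redundancy_removals
            ],
            "removal_reasons": [
                {"stage": s, "id": i, "reason": r} for s, i, r in self.removal_reasons
            ],
        }


@dataclass(frozen=True)
class RunConfig:
    """Everything one curation run needs; composable from YAML and CLI flags."""

    catalog_path: str | Path | None = None
    structures_dir: str | Path | None = None
    tblout_path: str | Path | None = None
    metadata: MetadataFilterConfig = field(default_factory=MetadataFilterConfig)
    chains: ChainFilterConfig = field(default_factory=ChainFilterConfig)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    redundancy: RedundancyConfig = field(default_factory=RedundancyConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    skip_redundancy: bool = False

    def validate_paths(self) -> None:
        for name in ("catalog_path", "structures_dir", "tblout_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


def _structure_file(structures_dir: Path, pdb_id: str) -> Path | None:
    for suffix in (".pdb", ".cif", ".ent", ".mmcif"):
        for candidate in (pdb_id, pdb_id.lower()):
            p = structures_dir / f"{candidate}{suffix}"
            if p.exists():
                return p
    return None


def build_dataset(
    config: RunConfig, catalog: Catalog | None = None
) -> tuple[list[DatasetEntry], StageReport]:
    """Run the full curation pipeline.

    Either *catalog* is given directly or ``config.catalog_path`` is loaded.
    Returns the curated chains sorted by (pdb_id, chain_id) and the
    per-stage :class:`StageReport`.  Any stage failure raises
    :class:`PipelineError` naming the stage; no partial outputs are written
    by this function (writers are separate).
    """
    config.validate_paths()
    if catalog is None:
        if config.catalog_path is None:
            raise PipelineError("stage catalog: no catalog given")
        catalog = load_catalog(config.catalog_path)

    stages: list[Stage] = []
    reasons: list[tuple[str, str, str]] = []

    # -- stage 1: entry-level metadata filter
    t0 = time.perf_counter()
    try:
        survivors, removed_meta = filter_metadata(catalog, config.metadata)
    except Exception as exc:
        raise PipelineError(f"stage metadata: {exc}") from exc
    stages.append(
        Stage("metadata", "entries", len(catalog), len(survivors), len(removed_meta),
              time.perf_counter() - t0)
    )
    reasons += [("metadata", pid, why) for pid, why in removed_meta]

    # -- stage 2: parse structures, chain-level filter
    t0 = time.perf_counter()
    all_chains: list[ChainRecord] = []
    n_chains_by_entry: dict[str, int] = {}
    if len(survivors) and config.structures_dir is None:
        raise PipelineError("stage chains: structures_dir not configured")
    for entry in survivors:
        path = _structure_file(Path(config.structures_dir), entry.pdb_id)
        if path is None:
            raise PipelineError(f"stage chains: no coordinate file for {entry.pdb_id}")
        try:
            chains = parse_structure(path, pdb_id=entry.pdb_id)
        except Exception as exc:
            raise PipelineError(f"stage chains: {entry.pdb_id}: {exc}") from exc
        n_chains_by_entry[entry.pdb_id] = len(chains)
        all_chains.extend(chains)
    kept_chains, removed_chains = filter_chains(all_chains, config.chains)
    stages.append(
        Stage("chain_filter", "chains", len(all_chains), len(kept_chains),
              len(removed_chains), time.perf_counter() - t0)
    )
    reasons += [("chain_filter", label, why) for label, why in removed_chains]

    # -- stage 3: SI redundancy
    t0 = time.perf_counter()
    removals: list[Removal] = []
    if kept_chains and not config.skip_redundancy:
        matrix = build_si_matrix(kept_chains, config.alignment)
        attrs = {
            c.label: LabelAttrs(
                resolution=catalog[c.pdb_id].resolution,
                release_year=catalog[c.pdb_id].release_year,
                label=c.label,
            )
            for c in kept_chains
        }
        kept_labels, removals = select_representatives(matrix, attrs, config.redundancy)
        kept_set = set(kept_labels)
        nr_chains = [c for c in kept_chains if c.label in kept_set]
    else:
        nr_chains = list(kept_chains)
    stages.append(
        Stage("si_redundancy", "chains", len(kept_chains), len(nr_chains),
              len(kept_chains) - len(nr_chains), time.perf_counter() - t0)
    )
    reasons += [("si_redundancy", r.removed, f"redundant-with:{r.kept}") for r in removals]

    # -- stage 4: Rfam annotation + family dedup
    t0 = time.perf_counter()
    entries = [
        DatasetEntry(
            pdb_id=c.pdb_id,
            chain_id=c.chain_id,
            sequence=c.sequence,
            length=c.length,
            resolution=catalog[c.pdb_id].resolution,
            experimental_method=catalog[c.pdb_id].experimental_method,
            release_year=catalog[c.pdb_id].release_year,
            n_chains_in_entry=n_chains_by_entry[c.pdb_id],
        )
        for c in nr_chains
    ]
    if config.tblout_path is not None:
        try:
            hits = parse_tblout(config.tblout_path)
        except Exception as exc:
            raise PipelineError(f"stage rfam: {exc}") from exc
        best = best_hit_per_query(hits)
        final, removed_fam = annotate_and_dedup(entries, best, config.annotation)
    else:
        final, removed_fam = list(entries), []
    stages.append(
        Stage("rfam_dedup", "chains", len(entries), len(final), len(removed_fam),
              time.perf_counter() - t0)
    )
    reasons += [("rfam_dedup", label, why) for label, why in removed_fam]

    final.sort(key=lambda e: (e.pdb_id, e.chain_id))
    report = StageReport(
        stages=tuple(stages),
        redundancy_removals=tuple(removals),
        removal_reasons=tuple(reasons),
    )
    for s in report.stages:
        logger.info("stage %-12s %-8s in=%d kept=%d removed=%d (%.3fs)",
                    s.name, s.unit, s.input_count, s.retained_count,
                    s.removed_count, s.elapsed_seconds)
    return final, report


# --- writers ---------------------------------------------------------------


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest form that round-trips exactly
    return str(value)


def write_dataset_tsv(entries: Sequence[DatasetEntry], path: str | Path) -> None:
    """Header + one tab-separated row per entry, in the fixed column order;
    absent optionals serialize as empty fields."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(DATASET_COLUMNS) + "\n")
        for e in entries:
            fh.write("\t".join(_fmt(getattr(e, col)) for col in DATASET_COLUMNS) + "\n")


def read_dataset_tsv(path: str | Path) -> list[DatasetEntry]:
    """Round-trip reader for :func:`write_dataset_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            DatasetEntry(
                pdb_id=row.pdb_id,
                chain_id=row.chain_id,
                sequence=row.sequence,
                length=int(row.length),
                resolution=float(row.resolution) if row.resolution else None,
                experimental_method=row.experimental_method,
                release_year=int(row.release_year),
                n_chains_in_entry=int(row.n_chains_in_entry),
                rfam_accession=row.rfam_accession or None,
                rfam_e_value=float(row.rfam_e_value) if row.rfam_e_value else None,
                rfam_bit_score=float(row.rfam_bit_score) if row.rfam_bit_score else None,
            )
        )
    return entries


def write_fasta(entries: Sequence[DatasetEntry], path: str | Path) -> None:
    """FASTA export in entry order, headers ``>pdbid_chainid``, 60-col wrap."""
    records = [
        SeqRecord(Seq(e.sequence), id=e.label, description="") for e in entries
    ]
    with Path(path).open("w", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "fasta")


def write_report_json(report: StageReport, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
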