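"""Rfam family annotation from Infernal ``cmscan --tblout`` output.

Each curated chain is searched against the Rfam covariance models with
``cmscan`` (run externally or through :func:`run_cmscan`); the tabular hit
file is parsed here.  A chain's family is its best hit — smallest E-value,
ties broken by larger bit score, then lexicographic accession.  Family-level
deduplication then keeps, among chains assigned to the same family, only
the one with the smallest E-value (ties: higher bit score, better
resolution, lexicographic id), which removes the residual redundancy that
sequence identity alone does not catch.  Chains without a significant hit
are retained unannotated by default.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .dataset import DatasetEntry

__all__ = [
    "FamilyHit",
    "AnnotationConfig",
    "run_cmscan",
    "parse_tblout",
    "best_hit_per_query",
    "annotate_and_dedup",
]

_ACCESSION_RE = re.compile(r"^RF\d{5}$")


class TbloutParseError(ValueError):
    """Malformed cmscan tblout content."""


@dataclass(frozen=True)
class FamilyHit:
    """One covariance-model hit of a chain against an Rfam family."""

    query_id: str
    rfam_accession: str
    family_name: str
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not _ACCESSION_RE.match(self.rfam_accession):
            raise ValueError(f"bad Rfam accession {self.rfam_accession!r}")
        if not self.e_value > 0:
            raise ValueError("e_value must be > 0")


@dataclass(frozen=True)
class AnnotationConfig:
    """``e_value_threshold`` bounds hit significance (default 0.01); hits
    above it are discarded and the chain stays unannotated.  With
    ``require_family`` the unannotated chains are dropped instead of kept."""

    e_value_threshold: float = 0.01
    dedup_per_family: bool = True
    require_family: bool = False

    def __post_init__(self) -> None:
        if not self.e_value_threshold > 0:
            raise ValueError("e_value_threshold must be > 0")


def run_cmscan(
    fasta_path: str | Path,
    cm_database_path: str | Path,
    tblout_path: str | Path,
    extra_options: Sequence[str] = (),
) -> Path:
    """Invoke the external Infernal ``cmscan`` binary; excluded from the
    offline test surface (tests parse recorded tblout files instead).

    Raises a ``FileNotFoundError`` naming the ``--tblout-file`` bypass when
    the binary is unavailable, and ``RuntimeError`` with captured
    diagnostics on a nonzero exit.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.is_file() or fasta_path.stat().st_size == 0:
        raise ValueError(f"empty or missing FASTA input: {fasta_path}")
    if shutil.which("cmscan") is None:
        raise FileNotFoundError(
            "cmscan binary not found; run Infernal elsewhere and pass the "
            "result via --tblout-file"
        )
    cmd = [
        "cmscan",
        "--tblout",
        str(tblout_path),
        *extra_options,
        str(cm_database_path),
        str(fasta_path),
    ]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"cmscan failed (exit {proc.returncode}):\n{proc.stderr}")
    return Path(tblout_path)


def parse_tblout(path: str | Path) -> list[FamilyHit]:
    """Parse an Infernal tblout (format 1) file into :class:`FamilyHit` rows.

    Columns used: target (family) name, target accession, query name, bit
    score (column 15) and E-value (column 16); ``#`` comment lines are
    skipped.  A malformed data line raises with its line number.
    """
    path = Path(path)
    hits: list[FamilyHit] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, 17)
            if len(fields) < 16:
                raise TbloutParseError(f"{path}:{lineno}: expected >= 16 fields")
            try:
                hits.append(
                    FamilyHit(
                        query_id=fields[2],
                        rfam_accession=fields[1],
                        family_name=fields[0],
                        bit_score=float(fields[14]),
                        e_value=float(fields[15]),
                    )
                )
            except ValueError as exc:
                raise TbloutParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def best_hit_per_query(hits: Sequence[FamilyHit]) -> dict[str, FamilyHit]:
    """Smallest E-value per query; ties by larger bit score, then accession."""
    best: dict[str, FamilyHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.query_id] = hit
    return best


def _hit_rank(hit: FamilyHit) -> tuple:
    return (hit.e_value, -hit.bit_score, hit.rfam_accession)


def annotate_and_dedup(
    entries: Sequence[DatasetEntry],
    best_hits: Mapping[str, FamilyHit],
    config: AnnotationConfig | None = None,
) -> tuple[list[DatasetEntry], list[tuple[str, str]]]:
    """Attach family annotations and deduplicate entries per family.

    Hits above the E-value threshold are discarded (the entry remains,
    unannotated).  With ``dedup_per_family``, among entries sharing an
    accession only the lowest-E-value one survives; the others are removed
    with reason ``family-dedup:<accession>``.  Unannotated entries are kept
    unless ``require_family`` is set (reason ``no-family``).  Survivors and
    removed always partition the input.
    """
    config = config or AnnotationConfig()
    annotated: list[DatasetEntry] = []
    for entry in entries:
        hit = best_hits.get(entry.label)
        if hit is not None and hit.e_value <= config.e_value_threshold:
            annotated.append(entry.with_hit(hit.rfam_accession, hit.e_value, hit.bit_score))
        else:
            annotated.append(entry)

    removed: list[tuple[str, str]] = []
    drop: set[str] = set()
    if config.require_family:
        for entry in annotated:
            if entry.rfam_accession is None:
                drop.add(entry.label)
                removed.append((entry.label, "no-family"))
    if config.dedup_per_family:
        by_family: dict[str, list[DatasetEntry]] = {}
        for entry in annotated:
            if entry.rfam_accession is not None and entry.label not in drop:
                by_family.setdefault(entry.rfam_accession, []).append(entry)
        for accession, members in sorted(by_family.items()):
            members.sort(key=_dedup_rank)
            for loser in members[1:]:
                drop.add(loser.label)
                removed.append((loser.label, f"family-dedup:{accession}"))
    survivors = [e for e in annotated if e.label not in drop]
    removed.sort(key=lambda r: r[0])
    return survivors, removed


def _dedup_rank(entry: DatasetEntry) -> tuple:
    import math

    return (
        entry.rfam_e_value,
        -(entry.rfam_bit_score if entry.rfam_bit_score is not None else -math.inf),
        entry.resolution is None,
        entry.resolution if entry.resolution is not None else math.inf,
        entry.label,
    )
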