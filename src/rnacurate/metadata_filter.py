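"""Entry-level (ENTRY) metadata filtering.

Predicates are evaluated in a fixed, documented order so removal reasons are
deterministic: method, resolution, year, entity types, keywords, RNA
subtypes.  An entry survives iff it passes every configured predicate.

Semantics that matter in practice:

* the resolution bound is strict ``<`` ("below" a threshold); entries with
  no resolution (typically NMR) fail an active resolution filter unless
  ``allow_missing_resolution`` is set;
* ``year_before`` is exclusive, ``year_range`` is inclusive at both ends;
* keyword matching is case-insensitive substring matching on the entry's
  free-text keyword field (any configured term suffices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .catalog import Catalog, EntryMeta

#: predicate evaluation order; the FIRST failing name is the removal reason
PREDICATE_ORDER = ("method", "resolution", "year", "entity_types", "keywords", "rna_subtypes")


class ConfigError(ValueError):
    """Invalid filter configuration."""


@dataclass(frozen=True)
class MetadataFilterConfig:
    """Which entry-level predicates are active; ``None``/empty means inactive."""

    methods: frozenset[str] | None = None
    max_resolution: float | None = None
    year_before: int | None = None
    year_range: tuple[int, int] | None = None
    required_entity_types: frozenset[str] | None = None
    forbidden_entity_types: frozenset[str] | None = None
    include_keywords: frozenset[str] | None = None
    exclude_keywords: frozenset[str] | None = None
    rna_subtypes: frozenset[str] | None = None
    allow_missing_resolution: bool = False

    def __post_init__(self) -> None:
        if self.year_before is not None and self.year_range is not None:
            raise ConfigError("year_before and year_range are mutually exclusive")
        if self.max_resolution is not None and not self.max_resolution > 0:
            raise ConfigError("max_resolution must be > 0")
        if self.year_range is not None and self.year_range[0] > self.year_range[1]:
            raise ConfigError("year_range start exceeds end")
        for name in ("methods", "required_entity_types", "forbidden_entity_types",
                     "include_keywords", "exclude_keywords", "rna_subtypes"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, frozenset(val))
        if self.methods is not None:
            object.__setattr__(self, "methods", frozenset(m.upper() for m in self.methods))


def _failing_predicate(entry: EntryMeta, cfg: MetadataFilterConfig) -> str | None:
    """Name of the first failing predicate in PREDICATE_ORDER, or None."""
    if cfg.methods is not None and entry.experimental_method not in cfg.methods:
        return "method"
    if cfg.max_resolution is not None:
        if entry.resolution is None:
            if not cfg.allow_missing_resolution:
                return "resolution"
        elif not entry.resolution < cfg.max_resolution:
            return "resolution"
    if cfg.year_before is not None and not entry.release_year < cfg.year_before:
        return "year"
    if cfg.year_range is not None and not (
        cfg.year_range[0] <= entry.release_year <= cfg.year_range[1]
    ):
        return "year"
    if cfg.required_entity_types is not None and not (
        cfg.required_entity_types <= entry.polymer_entity_types
    ):
        return "entity_types"
    if cfg.forbidden_entity_types is not None and (
        cfg.forbidden_entity_types & entry.polymer_entity_types
    ):
        return "entity_types"
    kw = entry.keywords.lower()
    if cfg.include_keywords is not None and not any(
        term.lower() in kw for term in cfg.include_keywords
    ):
        return "keywords"
    if cfg.exclude_keywords is not None and any(
        term.lower() in kw for term in cfg.exclude_keywords
    ):
        return "keywords"
    if cfg.rna_subtypes is not None:
        wanted = {s.lower() for s in cfg.rna_subtypes}
        have = {s.lower() for s in entry.rna_subtypes}
        if not wanted & have:
            return "rna_subtypes"
    return None


def filter_metadata(
    catalog: Catalog, config: MetadataFilterConfig
) -> tuple[Catalog, list[tuple[str, str]]]:
    """Partition *catalog* into survivors and removed-with-reason.

    Returns the surviving :class:`Catalog` (same snapshot label) and an
    ordered list of ``(pdb_id, reason)`` pairs, where *reason* is the first
    failing predicate in :data:`PREDICATE_ORDER`.  Survivors + removed
    always partition the input exactly.
    """
    kept: list[EntryMeta] = []
    removed: list[tuple[str, str]] = []
    for entry in catalog:
        reason = _failing_predicate(entry, config)
        if reason is None:
            kept.append(entry)
        else:
            removed.append((entry.pdb_id, reason))
    return (
        Catalog(entries=tuple(kept), snapshot_label=catalog.snapshot_label),
        removed,
    )
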