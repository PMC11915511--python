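"""Entry-level structure metadata: the catalog.

A :class:`Catalog` is the offline, pinned representation of the PDB entry
metadata the downstream filters consume (experimental method, resolution,
release year, polymer entity types, classification keywords, RNA subtypes).
It is stored as JSON-lines, one object per entry, so a run is reproducible
against a fixed snapshot.  A live adapter mirroring the RCSB Search API +
GraphQL attribute scheme is provided as an injectable boundary; no pipeline
stage ever talks to the network directly.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Canonical experimental-method strings; anything else is normalized to OTHER.
KNOWN_METHODS = ("X-RAY DIFFRACTION", "SOLUTION NMR", "ELECTRON MICROSCOPY")

KNOWN_ENTITY_TYPES = frozenset({"RNA", "DNA", "protein", "hybrid"})

_PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")


class CatalogError(ValueError):
    """Malformed or inconsistent catalog content."""


@dataclass(frozen=True)
class EntryMeta:
    """Metadata for one PDB entry.

    Parameters
    ----------
    pdb_id:
        Four-character accession; uppercased on construction.
    experimental_method:
        One of :data:`KNOWN_METHODS` or ``"OTHER"``.
    resolution:
        Resolution in Å; ``None`` for entries without one (most NMR).
    release_year:
        Calendar year of initial release.
    polymer_entity_types:
        Set of polymer entity type strings present in the entry.
    keywords:
        Free-text classification keyword string (``pdbx_keywords``-style).
    rna_subtypes:
        RNA subtype annotations (e.g. ``ncRNA``, ``rRNA``); may be empty.
    """

    pdb_id: str
    experimental_method: str = "OTHER"
    resolution: float | None = None
    release_year: int = 1971
    polymer_entity_types: frozenset[str] = frozenset()
    keywords: str = ""
    rna_subtypes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pdb_id", self.pdb_id.upper())
        if not _PDB_ID_RE.match(self.pdb_id):
            raise CatalogError(f"invalid pdb_id {self.pdb_id!r}")
        method = self.experimental_method.upper()
        if method not in KNOWN_METHODS:
            method = "OTHER" if method != "OTHER" else method
        object.__setattr__(self, "experimental_method", method)
        if self.resolution is not None and not self.resolution > 0:
            raise CatalogError(f"{self.pdb_id}: resolution must be > 0")
        if self.release_year < 1971:
            raise CatalogError(f"{self.pdb_id}: release_year before 1971")
        object.__setattr__(
            self, "polymer_entity_types", frozenset(self.polymer_entity_types)
        )
        object.__setattr__(self, "rna_subtypes", frozenset(self.rna_subtypes))

    def to_record(self) -> dict:
        """JSON-serializable record; absent optionals are omitted."""
        rec: dict = {
            "pdb_id": self.pdb_id,
            "experimental_method": self.experimental_method,
            "release_year": self.release_year,
            "polymer_entity_types": sorted(self.polymer_entity_types),
            "keywords": self.keywords,
            "rna_subtypes": sorted(self.rna_subtypes),
        }
        if self.resolution is not None:
            rec["resolution"] = self.resolution
        return rec

    @classmethod
    def from_record(cls, rec: Mapping) -> "EntryMeta":
        """Build from a parsed JSON object; unknown keys are ignored."""
        return cls(
            pdb_id=rec["pdb_id"],
            experimental_method=rec.get("experimental_method", "OTHER"),
            resolution=rec.get("resolution"),
            release_year=int(rec.get("release_year", 1971)),
            polymer_entity_types=frozenset(rec.get("polymer_entity_types", ())),
            keywords=rec.get("keywords", "") or "",
            rna_subtypes=frozenset(rec.get("rna_subtypes", ())),
        )


@dataclass(frozen=True)
class Catalog:
    """Ordered, pdb_id-unique collection of :class:`EntryMeta`."""

    entries: tuple[EntryMeta, ...] = ()
    snapshot_label: str = ""

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.entries, key=lambda e: e.pdb_id))
        seen: set[str] = set()
        dupes = sorted({e.pdb_id for e in ordered if e.pdb_id in seen or seen.add(e.pdb_id)})
        if dupes:
            raise CatalogError(f"duplicate pdb_id(s): {dupes}")
        object.__setattr__(self, "entries", ordered)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, pdb_id: str) -> EntryMeta:
        for e in self.entries:
            if e.pdb_id == pdb_id.upper():
                return e
        raise KeyError(pdb_id)

    def ids(self) -> list[str]:
        return [e.pdb_id for e in self.entries]


def load_catalog(path: str | Path) -> Catalog:
    """Load a JSON-lines catalog file.

    Each non-empty line must be one well-formed JSON object.  Unknown fields
    are ignored; missing optional fields (e.g. ``resolution``) stay absent.

    Raises
    ------
    CatalogError
        On a malformed line (with its line number) or a duplicate ``pdb_id``.
    """
    path = Path(path)
    entries: list[EntryMeta] = []
    snapshot = ""
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CatalogError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            if "snapshot_label" in rec and "pdb_id" not in rec:
                snapshot = str(rec["snapshot_label"])
                continue
            try:
                entries.append(EntryMeta.from_record(rec))
            except (KeyError, TypeError, ValueError) as exc:
                raise CatalogError(f"{path}:{lineno}: bad record: {exc}") from exc
    return Catalog(entries=tuple(entries), snapshot_label=snapshot)


def save_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write JSON-lines; ``load_catalog`` round-trips exactly."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if catalog.snapshot_label:
            fh.write(json.dumps({"snapshot_label": catalog.snapshot_label}) + "\n")
        for entry in catalog.entries:
            fh.write(json.dumps(entry.to_record(), sort_keys=True) + "\n")


# --------------------------------------------------------------------------
# Live adapter (RCSB Search API + GraphQL attributes).  Injectable so the
# offline test surface never touches the network.
# --------------------------------------------------------------------------

#: transport contract: search(methods, polymer_entry_type) -> list of ids;
#: attributes(ids) -> list of per-id records (dicts in EntryMeta.from_record form)
class Transport:
    def search(self, methods: Sequence[str], polymer_entry_type: str) -> list[str]:
        raise NotImplementedError

    def attributes(self, ids: Sequence[str]) -> list[dict]:
        raise NotImplementedError


class RcsbTransport(Transport):
    """Default HTTP transport against the public RCSB endpoints.

    Imported lazily; only the live path needs the ``requests`` package.
    """

    SEARCH_URL = "https://search.rcsb.org/rcsbsearch/v2/query"
    GRAPHQL_URL = "https://data.rcsb.org/graphql"

    def __init__(self, timeout: float = 30.0, retries: int = 3) -> None:
        self.timeout = timeout
        self.retries = retries

    def _post(self, url: str, payload: dict) -> dict:
        import requests  # local import: live mode only

        last: Exception | None = None
        for _ in range(self.retries):
            try:
                resp = requests.post(url, json=payload, timeout=self.timeout)
                resp.raise_for_status()
                return resp.json()
            except Exception as exc:  # noqa: BLE001 - retried, then re-raised
                last = exc
        raise ConnectionError(f"transport failure after {self.retries} tries: {last}")

    def search(self, methods: Sequence[str], polymer_entry_type: str) -> list[str]:
        nodes = [
            {
                "type": "terminal",
                "service": "text",
                "parameters": {
                    "attribute": "rcsb_entry_info.selected_polymer_entity_types",
                    "operator": "exact_match",
                    "value": polymer_entry_type,
                },
            }
        ]
        payload = {
            "query": {"type": "group", "logical_operator": "and", "nodes": nodes},
            "return_type": "entry",
            "request_options": {"return_all_hits": True},
        }
        data = self._post(self.SEARCH_URL, payload)
        return [hit["identifier"] for hit in data.get("result_set", [])]

    def attributes(self, ids: Sequence[str]) -> list[dict]:
        query = """
        query($ids: [String!]!) {
          entries(entry_ids: $ids) {
            rcsb_id
            exptl { method }
            rcsb_entry_info {
              resolution_combined
              selected_polymer_entity_types
            }
            struct_keywords { pdbx_keywords }
            rcsb_accession_info { initial_release_date }
          }
        }
        """
        data = self._post(self.GRAPHQL_URL, {"query": query, "variables": {"ids": list(ids)}})
        out = []
        for ent in data.get("data", {}).get("entries", []):
            res = (ent.get("rcsb_entry_info") or {}).get("resolution_combined") or []
            date = (ent.get("rcsb_accession_info") or {}).get("initial_release_date", "1971")
            out.append(
                {
                    "pdb_id": ent["rcsb_id"],
                    "experimental_method": (ent.get("exptl") or [{}])[0].get("method", "OTHER"),
                    "resolution": res[0] if res else None,
                    "release_year": int(str(date)[:4]),
                    "polymer_entity_types": [
                        (ent.get("rcsb_entry_info") or {}).get(
                            "selected_polymer_entity_types", ""
                        )
                    ],
                    "keywords": (ent.get("struct_keywords") or {}).get("pdbx_keywords", ""),
                }
            )
        return out


def fetch_live_catalog(
    method_filter: Iterable[str] = KNOWN_METHODS,
    polymer_entry_type: str = "RNA",
    transport: Transport | None = None,
    snapshot_label: str | None = None,
) -> Catalog:
    """Retrieve a catalog through the search + attribute adapter.

    With the default transport this queries the live RCSB endpoints; tests
    inject a recorded-response transport instead.  An empty id list yields an
    empty catalog (not an error).  Records missing a requested attribute are
    kept with the field absent and a warning logged.
    """
    if transport is None:
        transport = RcsbTransport()
    methods = [m.upper() for m in method_filter]
    ids = transport.search(methods, polymer_entry_type)
    if not ids:
        return Catalog(entries=(), snapshot_label=snapshot_label or "")
    entries = []
    for rec in transport.attributes(ids):
        if "resolution" not in rec or rec.get("resolution") is None:
            logger.warning("entry %s: no resolution attribute", rec.get("pdb_id"))
        entries.append(EntryMeta.from_record(rec))
    if snapshot_label is None:
        import datetime

        snapshot_label = f"live-{datetime.date.today().isoformat()}"
    return Catalog(entries=tuple(entries), snapshot_label=snapshot_label)
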