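"""Per-structure (INSTANCE) parsing and chain-level filtering.

Coordinate files in PDB or mmCIF dialect are read with gemmi.  For each
polymer chain we record an uppercase one-letter sequence (RNA alphabet
``A C G U N``), its length, a polymer classification, and whether residues
are missing from the observed coordinates relative to the full polymer
sequence record (SEQRES / ``entity_poly``).

Sequence source precedence: the full polymer sequence record wins over the
observed residues, because redundancy comparison should see the full
construct; the two are compared to flag unresolved residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi

__all__ = [
    "ChainRecord",
    "ChainFilterConfig",
    "parse_structure",
    "normalize_residue",
    "classify_polymer",
    "filter_chains",
    "load_parent_table",
]


class StructureParseError(ValueError):
    """Unreadable or malformed coordinate file."""


# --- residue vocabulary ----------------------------------------------------

_RNA_STANDARD = {"A": "A", "C": "C", "G": "G", "U": "U", "N": "N"}
_DNA_STANDARD = {"DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U", "DN": "N"}
_AMINO = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL MSE SEC PYL UNK".split()
)


def load_parent_table(extra: str | Path | None = None) -> dict[str, str]:
    """Bundled modified-ribonucleotide parent table, optionally extended.

    The table maps CCD component ids of common modified ribonucleotides to
    their parent base letter; *extra* points at a user TSV of the same
    two-column format whose rows override/extend the bundled ones.
    """
    table: dict[str, str] = {}

    def _read(lines: Iterable[str]) -> None:
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code, parent = line.split("\t")
            table[code.strip().upper()] = parent.strip().upper()

    ref = resources.files("rnacurate").joinpath("data/modified_nucleotides.tsv")
    _read(ref.read_text(encoding="utf-8").splitlines())
    if extra is not None:
        _read(Path(extra).read_text(encoding="utf-8").splitlines())
    return table


_PARENTS = load_parent_table()


def normalize_residue(code: str, parents: dict[str, str] | None = None) -> str:
    """Map a residue name to one letter of ``{A, C, G, U, N}``.

    Standard ribonucleotides map to themselves; modified ribonucleotides map
    to their parent base through the bundled (user-extensible) table; every
    other code maps to ``N``.  Total and deterministic.
    """
    code = code.strip().upper()
    if code in _RNA_STANDARD:
        return _RNA_STANDARD[code]
    parent = (parents or _PARENTS).get(code)
    if parent in ("A", "C", "G", "U"):
        return parent
    return "N"


def _residue_class(code: str, parents: dict[str, str] | None = None) -> str:
    code = code.strip().upper()
    if code in _DNA_STANDARD:
        return "dna"
    if code in _RNA_STANDARD or code in (parents or _PARENTS):
        return "rna"
    if code in _AMINO:
        return "amino"
    return "unknown"


def classify_polymer(residue_codes: Sequence[str]) -> str:
    """Classify a chain from its residue codes.

    Returns one of ``RNA``, ``DNA``, ``protein``, ``hybrid``, ``other``.
    Unknown codes are class-neutral (they become ``N`` in the sequence);
    chains mixing ribo- and deoxyribonucleotides are ``hybrid``; chains
    mixing nucleotides with amino acids, or containing nothing classifiable,
    are ``other``.
    """
    if not residue_codes:
        raise ValueError("empty residue collection")
    classes = {_residue_class(c) for c in residue_codes}
    classes.discard("unknown")
    if classes == {"rna"}:
        return "RNA"
    if classes == {"dna"}:
        return "DNA"
    if classes == {"amino"}:
        return "protein"
    if classes == {"rna", "dna"}:
        return "hybrid"
    return "other"


# --- chain records ---------------------------------------------------------


@dataclass(frozen=True)
class ChainRecord:
    """One polymer chain instance of an entry."""

    pdb_id: str
    chain_id: str
    polymer_class: str
    sequence: str
    length: int
    has_unresolved_residues: bool = False

    @property
    def label(self) -> str:
        return f"{self.pdb_id}_{self.chain_id}"

    @property
    def unknown_fraction(self) -> float:
        if not self.sequence:
            return 0.0
        return self.sequence.count("N") / len(self.sequence)


@dataclass(frozen=True)
class ChainFilterConfig:
    """Chain-level inclusion criteria.

    ``min_length`` defaults to 20 residues, the conventional cut below which
    structured-RNA chains are considered uninformatively short; the bound is
    inclusive (a chain of exactly ``min_length`` is kept).
    """

    target_polymer_class: str = "RNA"
    min_length: int = 20
    max_unknown_fraction: float = 0.1
    require_no_unresolved: bool = False

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0.0 <= self.max_unknown_fraction <= 1.0:
            raise ValueError("max_unknown_fraction must be in [0, 1]")


def parse_structure(
    path: str | Path,
    pdb_id: str | None = None,
    parents: dict[str, str] | None = None,
) -> list[ChainRecord]:
    """Extract polymer chains from a PDB or mmCIF coordinate file.

    Returns one :class:`ChainRecord` per distinct polymer chain in file
    order; non-polymer components (waters, ions, ligands) are excluded.
    Only the first model of multi-model (NMR) files is read.  A file with
    zero polymer chains yields an empty list.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    if pdb_id is None:
        pdb_id = (st.name or path.stem)[:4].upper()
    if len(st) == 0:
        return []
    model = st[0]
    records: list[ChainRecord] = []
    seen: set[str] = set()
    for chain in model:
        if chain.name in seen:  # duplicate chain id: first model/occurrence wins
            continue
        polymer = chain.get_polymer()
        if len(polymer) == 0:
            continue
        seen.add(chain.name)
        entity = st.get_entity_of(polymer)
        full_codes: list[str] = []
        if entity is not None and entity.full_sequence:
            full_codes = [gemmi.Entity.first_mon(item) for item in entity.full_sequence]
        observed_codes = [res.name for res in polymer]
        codes = full_codes if full_codes else observed_codes
        unresolved = _has_unresolved(full_codes, polymer)
        cls = classify_polymer(codes)
        if cls in ("RNA", "hybrid"):
            seq = "".join(normalize_residue(c, parents) for c in codes)
        elif cls == "DNA":
            seq = "".join(_DNA_STANDARD.get(c.strip().upper(), "N") for c in codes)
        else:
            seq = "X" * len(codes)
        records.append(
            ChainRecord(
                pdb_id=pdb_id,
                chain_id=chain.name,
                polymer_class=cls,
                sequence=seq,
                length=len(codes),
                has_unresolved_residues=unresolved,
            )
        )
    return records


def _has_unresolved(full_codes: list[str], polymer) -> bool:
    """Residues missing from coordinates, by SEQRES mismatch or numbering gaps."""
    if full_codes and len(polymer) != len(full_codes):
        return True
    nums = [res.seqid.num for res in polymer]
    return any(b - a > 1 for a, b in zip(nums, nums[1:]))


def filter_chains(
    chains: Sequence[ChainRecord], config: ChainFilterConfig | None = None
) -> tuple[list[ChainRecord], list[tuple[str, str]]]:
    """Partition chains into kept and removed-with-reason.

    A chain is kept iff its polymer class matches the target, its length is
    at least ``min_length``, its fraction of unknown (``N``) residues is at
    most ``max_unknown_fraction``, and — when ``require_no_unresolved`` —
    it has no unresolved residues.  Reasons name the first failing check in
    that order.
    """
    config = config or ChainFilterConfig()
    kept: list[ChainRecord] = []
    removed: list[tuple[str, str]] = []
    for chain in chains:
        if chain.polymer_class != config.target_polymer_class:
            removed.append((chain.label, "polymer_class"))
        elif chain.length < config.min_length:
            removed.append((chain.label, "length"))
        elif chain.unknown_fraction > config.max_unknown_fraction:
            removed.append((chain.label, "unknown_fraction"))
        elif config.require_no_unresolved and chain.has_unresolved_residues:
            removed.append((chain.label, "unresolved"))
        else:
            kept.append(chain)
    return kept, removed
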