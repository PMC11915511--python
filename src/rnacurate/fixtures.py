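"""Synthetic corpora with planted ground truth.

Because the real inputs (a dated PDB snapshot, Infernal runs against Rfam)
are not reproducible at desk scale, correctness of the pipeline is
established against corpora whose outcome is known *by construction*: the
generator writes a catalog, one coordinate file per entry and an optional
cmscan tblout, and independently computes the expected survivor set and
per-stage counts by replaying the documented filter rules in a second,
deliberately separate code path (:func:`replay_truth`).

Redundancy structure is planted through groups: chains in the same group
are point-mutated copies of a common seed sequence (no indels, so identity
stays analytically predictable), chains in different groups are independent
random sequences.  The planted SI relationships are verified post hoc with
the package's pairwise identity — itself oracle-verified at small lengths —
and offending sequences are redrawn; a corpus that cannot be realized
within the retry budget raises instead of being silently wrong.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import Catalog, EntryMeta, save_catalog
from .metadata_filter import MetadataFilterConfig
from .pipeline import RunConfig
from .redundancy import RedundancyConfig
from .rfam_annotation import AnnotationConfig
from .seq_identity import AlignmentParams, pairwise_identity
from .structure_parser import ChainFilterConfig

__all__ = [
    "ChainPlan",
    "EntryPlan",
    "FixtureSpec",
    "FixtureTruth",
    "generate_corpus",
    "replay_truth",
    "run_config_for",
    "random_fixture_spec",
]

_AMINO20 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()
_DNA4 = ("DA", "DC", "DG", "DT")

#: substitution rate within a redundancy group (keeps within-group SI ~>85%)
GROUP_MUTATION_RATE = 0.08


class FixtureError(RuntimeError):
    """Unsatisfiable fixture specification."""


@dataclass(frozen=True)
class ChainPlan:
    chain_id: str
    polymer_class: str = "RNA"  # RNA | DNA | protein
    length: int = 30
    unknown_fraction: float = 0.0
    redundancy_group: str | None = None
    family: tuple[str, float, float] | None = None  # (accession, e_value, bit_score)
    n_unresolved: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0 <= self.n_unresolved < self.length:
            raise ValueError("n_unresolved must be < length")


@dataclass(frozen=True)
class EntryPlan:
    pdb_id: str
    method: str = "X-RAY DIFFRACTION"
    resolution: float | None = 2.0
    year: int = 2015
    keywords: str = "RNA"
    rna_subtypes: tuple[str, ...] = ()
    chains: tuple[ChainPlan, ...] = ()


@dataclass(frozen=True)
class FixtureSpec:
    """A corpus plan plus the filter settings it is engineered against."""

    entries: tuple[EntryPlan, ...]
    seed: int = 0
    si_threshold: float = 50.0
    min_length: int = 20
    max_resolution: float | None = 3.6
    methods: tuple[str, ...] | None = ("X-RAY DIFFRACTION",)
    include_keywords: tuple[str, ...] | None = None
    e_value_threshold: float = 0.01
    max_unknown_fraction: float = 0.1

    def __post_init__(self) -> None:
        groups: dict[str, int] = {}
        for entry in self.entries:
            for chain in entry.chains:
                if chain.redundancy_group:
                    groups[chain.redundancy_group] = groups.get(chain.redundancy_group, 0) + 1
        if any(n < 1 for n in groups.values()):
            raise ValueError("redundancy groups must reference at least one chain")


@dataclass(frozen=True)
class FixtureTruth:
    """Expected pipeline outcome, computed by independent rule replay."""

    survivors: tuple[str, ...]  # labels pdbid_chainid
    stage_counts: Mapping[str, Mapping[str, int]]
    removal_reasons: Mapping[str, str]  # id (pdb_id or label) -> reason
    annotations: Mapping[str, str]  # surviving label -> rfam accession

    def to_json_dict(self) -> dict:
        return {
            "survivors": list(self.survivors),
            "stage_counts": {k: dict(v) for k, v in self.stage_counts.items()},
            "removal_reasons": dict(self.removal_reasons),
            "annotations": dict(self.annotations),
        }


def run_config_for(spec: FixtureSpec, corpus_dir: str | Path) -> RunConfig:
    """The RunConfig a corpus was engineered for."""
    corpus_dir = Path(corpus_dir)
    tblout = corpus_dir / "hits.tblout"
    return RunConfig(
        catalog_path=corpus_dir / "catalog.jsonl",
        structures_dir=corpus_dir / "structures",
        tblout_path=tblout if tblout.exists() else None,
        metadata=MetadataFilterConfig(
            methods=frozenset(spec.methods) if spec.methods else None,
            max_resolution=spec.max_resolution,
            include_keywords=frozenset(spec.include_keywords) if spec.include_keywords else None,
        ),
        chains=ChainFilterConfig(
            min_length=spec.min_length, max_unknown_fraction=spec.max_unknown_fraction
        ),
        redundancy=RedundancyConfig(si_threshold=spec.si_threshold),
        annotation=AnnotationConfig(e_value_threshold=spec.e_value_threshold),
    )


# --------------------------------------------------------------------------
# independent rule replay (the oracle)
# --------------------------------------------------------------------------


def _meta_reason(entry: EntryPlan, spec: FixtureSpec) -> str | None:
    if spec.methods is not None and entry.method.upper() not in {
        m.upper() for m in spec.methods
    }:
        return "method"
    if spec.max_resolution is not None:
        if entry.resolution is None or not entry.resolution < spec.max_resolution:
            return "resolution"
    if spec.include_keywords is not None and not any(
        term.lower() in entry.keywords.lower() for term in spec.include_keywords
    ):
        return "keywords"
    return None


def _chain_reason(chain: ChainPlan, n_unknown: int, spec: FixtureSpec) -> str | None:
    if chain.polymer_class != "RNA":
        return "polymer_class"
    if chain.length < spec.min_length:
        return "length"
    if n_unknown / chain.length > spec.max_unknown_fraction:
        return "unknown_fraction"
    return None


def _planted_unknown_count(chain: ChainPlan) -> int:
    return int(round(chain.unknown_fraction * chain.length))


def replay_truth(spec: FixtureSpec) -> FixtureTruth:
    """Replay the documented filter rules on the plan, without the pipeline.

    Redundancy is resolved per planted group: since cross-group SI is
    engineered (and verified) to stay below the threshold, the greedy rule
    keeps exactly the best-ranked member of each group — smallest
    resolution (absent last), then earliest year, then smallest label —
    plus every ungrouped chain.
    """
    reasons: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {}

    meta_kept: list[EntryPlan] = []
    for entry in spec.entries:
        why = _meta_reason(entry, spec)
        if why is None:
            meta_kept.append(entry)
        else:
            reasons[entry.pdb_id.upper()] = why
    counts["metadata"] = {
        "input": len(spec.entries),
        "retained": len(meta_kept),
        "removed": len(spec.entries) - len(meta_kept),
    }

    chain_pool: list[tuple[EntryPlan, ChainPlan]] = [
        (e, c) for e in meta_kept for c in e.chains
    ]
    chain_kept: list[tuple[EntryPlan, ChainPlan]] = []
    for entry, chain in chain_pool:
        label = f"{entry.pdb_id.upper()}_{chain.chain_id}"
        why = _chain_reason(chain, _planted_unknown_count(chain), spec)
        if why is None:
            chain_kept.append((entry, chain))
        else:
            reasons[label] = why
    counts["chain_filter"] = {
        "input": len(chain_pool),
        "retained": len(chain_kept),
        "removed": len(chain_pool) - len(chain_kept),
    }

    def rank(item: tuple[EntryPlan, ChainPlan]) -> tuple:
        entry, chain = item
        return (
            entry.resolution is None,
            entry.resolution if entry.resolution is not None else math.inf,
            entry.year,
            f"{entry.pdb_id.upper()}_{chain.chain_id}",
        )

    by_group: dict[str, list[tuple[EntryPlan, ChainPlan]]] = {}
    nr_kept: list[tuple[EntryPlan, ChainPlan]] = []
    for entry, chain in chain_kept:
        if chain.redundancy_group:
            by_group.setdefault(chain.redundancy_group, []).append((entry, chain))
        else:
            nr_kept.append((entry, chain))
    for members in by_group.values():
        members.sort(key=rank)
        winner = members[0]
        nr_kept.append(winner)
        win_label = f"{winner[0].pdb_id.upper()}_{winner[1].chain_id}"
        for entry, chain in members[1:]:
            reasons[f"{entry.pdb_id.upper()}_{chain.chain_id}"] = (
                f"redundant-with:{win_label}"
            )
    counts["si_redundancy"] = {
        "input": len(chain_kept),
        "retained": len(nr_kept),
        "removed": len(chain_kept) - len(nr_kept),
    }

    significant = [
        (entry, chain)
        for entry, chain in nr_kept
        if chain.family is not None and chain.family[1] <= spec.e_value_threshold
    ]
    by_family: dict[str, list[tuple[EntryPlan, ChainPlan]]] = {}
    for entry, chain in significant:
        by_family.setdefault(chain.family[0], []).append((entry, chain))

    def fam_rank(item: tuple[EntryPlan, ChainPlan]) -> tuple:
        entry, chain = item
        _, e_value, bit = chain.family  # type: ignore[misc]
        return (
            e_value,
            -bit,
            entry.resolution is None,
            entry.resolution if entry.resolution is not None else math.inf,
            f"{entry.pdb_id.upper()}_{chain.chain_id}",
        )

    dropped: set[str] = set()
    annotations: dict[str, str] = {}
    for accession, members in sorted(by_family.items()):
        members.sort(key=fam_rank)
        annotations[f"{members[0][0].pdb_id.upper()}_{members[0][1].chain_id}"] = accession
        for entry, chain in members[1:]:
            label = f"{entry.pdb_id.upper()}_{chain.chain_id}"
            dropped.add(label)
            reasons[label] = f"family-dedup:{accession}"
    final = [
        (entry, chain)
        for entry, chain in nr_kept
        if f"{entry.pdb_id.upper()}_{chain.chain_id}" not in dropped
    ]
    counts["rfam_dedup"] = {
        "input": len(nr_kept),
        "retained": len(final),
        "removed": len(nr_kept) - len(final),
    }

    survivors = tuple(
        sorted(f"{entry.pdb_id.upper()}_{chain.chain_id}" for entry, chain in final)
    )
    return FixtureTruth(
        survivors=survivors,
        stage_counts=counts,
        removal_reasons=reasons,
        annotations=annotations,
    )


# --------------------------------------------------------------------------
# sequence planting
# --------------------------------------------------------------------------


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def _plant_unknowns(rng: np.random.Generator, seq: str, n_unknown: int) -> str:
    if n_unknown == 0:
        return seq
    positions = rng.choice(len(seq), size=n_unknown, replace=False)
    chars = list(seq)
    for p in positions:
        chars[p] = "N"
    return "".join(chars)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    for i, c in enumerate(chars):
        if rng.random() < rate:
            chars[i] = rng.choice([b for b in "ACGU" if b != c])
    return "".join(chars)


def _plant_sequences(
    spec: FixtureSpec,
    rng: np.random.Generator,
    params: AlignmentParams,
    max_retries: int = 200,
) -> dict[str, str]:
    """Sequences for every RNA chain, honoring group SI structure.

    Only chains that reach the SI stage (per the replay) take part in the
    verified above/below-threshold constraints; other chains just get a
    random draw (grouped ones still a mutated group copy, for realism).
    """
    truth_chain_stage: set[str] = set()
    for entry in spec.entries:
        if _meta_reason(entry, spec) is not None:
            continue
        for chain in entry.chains:
            if _chain_reason(chain, _planted_unknown_count(chain), spec) is None:
                truth_chain_stage.add(f"{entry.pdb_id.upper()}_{chain.chain_id}")

    plans: dict[str, ChainPlan] = {}
    for entry in spec.entries:
        for chain in entry.chains:
            if chain.polymer_class == "RNA":
                plans[f"{entry.pdb_id.upper()}_{chain.chain_id}"] = chain

    group_labels: dict[str, list[str]] = {}
    for label, chain in plans.items():
        if chain.redundancy_group:
            group_labels.setdefault(chain.redundancy_group, []).append(label)

    group_seed: dict[str, str] = {}
    for group, labels in sorted(group_labels.items()):
        seed_len = max(plans[lab].length for lab in labels)
        group_seed[group] = _random_rna(rng, seed_len)

    def draw(label: str) -> str:
        chain = plans[label]
        if chain.redundancy_group:
            base = group_seed[chain.redundancy_group][: chain.length]
            seq = _mutate(rng, base, GROUP_MUTATION_RATE)
        else:
            seq = _random_rna(rng, chain.length)
        return _plant_unknowns(rng, seq, _planted_unknown_count(chain))

    seqs = {label: draw(label) for label in sorted(plans)}

    active = sorted(truth_chain_stage & set(seqs))
    budget = max_retries
    while True:
        violation = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                same = (
                    plans[a].redundancy_group is not None
                    and plans[a].redundancy_group == plans[b].redundancy_group
                )
                si = pairwise_identity(seqs[a], seqs[b], params)
                if same and not si > spec.si_threshold:
                    violation = a if a != min(a, b) else b
                elif not same and not si < spec.si_threshold:
                    violation = max(a, b)
                if violation:
                    break
            if violation:
                break
        if violation is None:
            return seqs
        if budget == 0:
            raise FixtureError(
                f"could not realize the planted SI structure for {violation} "
                f"within the retry budget"
            )
        budget -= 1
        seqs[violation] = draw(violation)


# --------------------------------------------------------------------------
# file writers (PDB dialect, catalog, tblout)
# --------------------------------------------------------------------------


def _seqres_lines(chain_id: str, codes: Sequence[str]) -> list[str]:
    lines = []
    for i in range(0, len(codes), 13):
        block = codes[i : i + 13]
        lines.append(
            f"SEQRES {i // 13 + 1:>3} {chain_id} {len(codes):>4}  "
            + " ".join(f"{c:>3}" for c in block)
        )
    return lines


def _atom_line(
    serial: int, name: str, resname: str, chain_id: str, resseq: int,
    x: float, y: float, z: float, element: str, het: bool = False,
) -> str:
    rec = "HETATM" if het else "ATOM  "
    return (
        f"{rec}{serial:>5}  {name:<3} {resname:>3} {chain_id}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}"
    )


def _chain_codes(chain: ChainPlan, seq: str | None, rng: np.random.Generator) -> list[str]:
    if chain.polymer_class == "RNA":
        assert seq is not None
        return list(seq)
    if chain.polymer_class == "DNA":
        return [str(rng.choice(_DNA4)) for _ in range(chain.length)]
    return [str(rng.choice(_AMINO20)) for _ in range(chain.length)]


def _write_pdb(
    path: Path, entry: EntryPlan, codes_by_chain: dict[str, list[str]]
) -> None:
    lines = [f"HEADER    RNA FIXTURE                             01-JAN-15   {entry.pdb_id.upper()}"]
    for chain in entry.chains:
        lines += _seqres_lines(chain.chain_id, codes_by_chain[chain.chain_id])
    serial = 1
    for chain in entry.chains:
        codes = codes_by_chain[chain.chain_id]
        # leave out a run of interior residues to plant unresolved gaps
        skip_from = (len(codes) - chain.n_unresolved) // 2
        skipped = range(skip_from, skip_from + chain.n_unresolved)
        atom = "CA" if chain.polymer_class == "protein" else "C1'"
        element = "C"
        for i, code in enumerate(codes):
            if i in skipped:
                continue
            lines.append(
                _atom_line(serial, atom, code, chain.chain_id, i + 1,
                           3.0 * i, 0.0, 0.0, element)
            )
            serial += 1
        lines.append("TER")
    lines.append(_atom_line(serial, "O", "HOH", "Z", 1, 0.0, 8.0, 8.0, "O", het=True))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _entity_types(entry: EntryPlan) -> list[str]:
    types = set()
    for chain in entry.chains:
        if chain.polymer_class in ("RNA", "DNA"):
            types.add(chain.polymer_class)
        elif chain.polymer_class == "protein":
            types.add("protein")
    return sorted(types)


_TBLOUT_HEADER = (
    "#target name         accession query name           accession mdl mdl from"
    "   mdl to seq from   seq to strand trunc pass   gc  bias  score   E-value inc"
    " description of target\n"
    "#------------------- --------- -------------------- --------- --- --------"
    " -------- -------- -------- ------ ----- ---- ---- ----- ------ --------- ---"
    " ---------------------\n"
)


def _write_tblout(path: Path, spec: FixtureSpec) -> bool:
    rows = []
    for entry in spec.entries:
        for chain in entry.chains:
            if chain.family is None:
                continue
            accession, e_value, bit = chain.family
            label = f"{entry.pdb_id.upper()}_{chain.chain_id}"
            rows.append(
                f"fam-{accession[2:]}        {accession}   {label:<20} -         cm"
                f"        1       {chain.length}        1       {chain.length}"
                f"      +    no    1 0.50   0.0  {format(bit, '.17g')} "
                f"{format(e_value, '.17g')} ! planted fixture hit\n"
            )
    if not rows:
        return False
    path.write_text(_TBLOUT_HEADER + "".join(rows), encoding="utf-8")
    return True


def generate_corpus(spec: FixtureSpec, out_dir: str | Path) -> FixtureTruth:
    """Write a self-contained corpus directory and return its planted truth.

    Layout: ``catalog.jsonl``, ``structures/<pdbid>.pdb``, optionally
    ``hits.tblout``, plus ``truth.json`` (the serialized truth).  Identical
    (spec, seed) produce byte-identical corpora.
    """
    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    seqs = _plant_sequences(spec, rng, AlignmentParams())

    entries_meta = []
    for entry in spec.entries:
        codes_by_chain = {
            chain.chain_id: _chain_codes(
                chain, seqs.get(f"{entry.pdb_id.upper()}_{chain.chain_id}"), rng
            )
            for chain in entry.chains
        }
        _write_pdb(out_dir / "structures" / f"{entry.pdb_id.upper()}.pdb",
                   entry, codes_by_chain)
        entries_meta.append(
            EntryMeta(
                pdb_id=entry.pdb_id,
                experimental_method=entry.method,
                resolution=entry.resolution,
                release_year=entry.year,
                polymer_entity_types=frozenset(_entity_types(entry)),
                keywords=entry.keywords,
                rna_subtypes=frozenset(entry.rna_subtypes),
            )
        )
    save_catalog(
        Catalog(entries=tuple(entries_meta), snapshot_label=f"fixture-seed-{spec.seed}"),
        out_dir / "catalog.jsonl",
    )
    _write_tblout(out_dir / "hits.tblout", spec)

    truth = replay_truth(spec)
    with (out_dir / "truth.json").open("w", encoding="utf-8") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth


# --------------------------------------------------------------------------
# randomized specs for property-based testing
# --------------------------------------------------------------------------


def random_fixture_spec(seed: int, max_entries: int = 15) -> FixtureSpec:
    """A randomized but always-satisfiable corpus plan.

    Plants, with seed-dependent frequencies: entries failing the metadata
    filter (wrong method or resolution too coarse), chains failing the
    chain filter (non-RNA, too short, too many unknowns), redundancy groups
    spanning entries, and shared Rfam families with distinct E-values.
    """
    rng = np.random.default_rng(seed)
    n_entries = int(rng.integers(2, max_entries + 1))
    n_groups = int(rng.integers(0, max(1, n_entries // 3) + 1))
    group_names = [f"g{i}" for i in range(n_groups)]
    group_len = {g: int(rng.integers(28, 61)) for g in group_names}
    families = [f"RF{10000 + i:05d}" for i in range(3)]

    entries = []
    chain_letters = "ABCDEF"
    for i in range(n_entries):
        pdb_id = f"{1 + i % 9}F{i:02d}"[:4]
        roll = rng.random()
        if roll < 0.15:
            method, resolution = "SOLUTION NMR", None
        elif roll < 0.3:
            method, resolution = "X-RAY DIFFRACTION", float(np.round(rng.uniform(3.6, 5.0), 2))
        else:
            method, resolution = "X-RAY DIFFRACTION", float(np.round(rng.uniform(1.5, 3.5), 2))
        n_chains = int(rng.integers(1, 4))
        chains = []
        for j in range(n_chains):
            cid = chain_letters[j]
            croll = rng.random()
            if croll < 0.12:
                chains.append(ChainPlan(cid, polymer_class=str(rng.choice(["protein", "DNA"])),
                                        length=int(rng.integers(20, 50))))
            elif croll < 0.24:
                chains.append(ChainPlan(cid, length=int(rng.integers(5, 20))))
            elif croll < 0.32:
                chains.append(ChainPlan(cid, length=int(rng.integers(25, 50)),
                                        unknown_fraction=0.3))
            else:
                group = None
                if group_names and rng.random() < 0.5:
                    group = str(rng.choice(group_names))
                length = group_len[group] if group else int(rng.integers(25, 61))
                family = None
                if rng.random() < 0.5:
                    family = (
                        str(rng.choice(families)),
                        float(10.0 ** rng.uniform(-12, -3)),
                        float(np.round(rng.uniform(30, 90), 1)),
                    )
                chains.append(
                    ChainPlan(cid, length=length, redundancy_group=group, family=family,
                              n_unresolved=int(rng.integers(0, 3)))
                )
        entries.append(
            EntryPlan(
                pdb_id=pdb_id, method=method, resolution=resolution,
                year=int(rng.integers(1995, 2025)), chains=tuple(chains),
            )
        )
    return FixtureSpec(entries=tuple(entries), seed=int(rng.integers(0, 2**31 - 1)))
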