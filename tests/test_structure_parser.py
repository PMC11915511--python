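"""Coordinate parsing, residue normalization, polymer classification, chain filter."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rnacurate.structure_parser import (
    ChainFilterConfig,
    ChainRecord,
    StructureParseError,
    classify_polymer,
    filter_chains,
    load_parent_table,
    normalize_residue,
    parse_structure,
)

# -- minimal hand-rolled PDB text, independent of the package's writer -------


def seqres(chain_id, codes):
    lines = []
    for i in range(0, len(codes), 13):
        block = codes[i : i + 13]
        lines.append(
            f"SEQRES {i // 13 + 1:>3} {chain_id} {len(codes):>4}  "
            + " ".join(f"{c:>3}" for c in block)
        )
    return lines


def atoms(codes, chain_id, start_serial=1, atom="C1'", skip=(), het=False, resname=None):
    lines = []
    serial = start_serial
    rec = "HETATM" if het else "ATOM  "
    for i, code in enumerate(codes):
        if i in skip:
            continue
        name = resname or code
        lines.append(
            f"{rec}{serial:>5}  {atom:<3} {name:>3} {chain_id}{i + 1:>4}    "
            f"{3.0 * i:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{0.0:6.2f}           C"
        )
        serial += 1
    return lines, serial


def write_pdb(path, chains, waters=True):
    """chains: list of (chain_id, codes, atom_name, skip_indices)."""
    lines = []
    for cid, codes, *_ in chains:
        lines += seqres(cid, codes)
    serial = 1
    for cid, codes, atom, skip in chains:
        block, serial = atoms(codes, cid, serial, atom=atom, skip=skip)
        lines += block
        lines.append("TER")
    if waters:
        lines.append(
            f"HETATM{serial:>5}  O   HOH Z   1    {0.0:8.3f}{8.0:8.3f}{8.0:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}           O"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


RNA25 = list("ACGUACGUACGUACGUACGUACGUA")
PROT22 = "ALA GLY SER THR VAL LEU ILE PHE TYR TRP LYS ARG HIS ASP GLU ALA GLY SER THR VAL ALA GLY".split()
DNA22 = ("DA DC DG DT " * 6).split()[:22]


class TestParseStructure:
    def test_single_rna_chain_with_water(self, tmp_path):
        path = write_pdb(tmp_path / "1aaa.pdb", [("A", RNA25, "C1'", ())])
        records = parse_structure(path, pdb_id="1AAA")
        assert len(records) == 1
        rec = records[0]
        assert (rec.chain_id, rec.polymer_class, rec.length) == ("A", "RNA", 25)
        assert rec.sequence == "".join(RNA25)
        assert not rec.has_unresolved_residues

    def test_protein_rna_complex(self, tmp_path):
        path = write_pdb(tmp_path / "2bbb.pdb",
                         [("A", PROT22, "CA", ()), ("B", RNA25, "C1'", ())])
        records = parse_structure(path, pdb_id="2BBB")
        assert [r.polymer_class for r in records] == ["protein", "RNA"]

    def test_dna_chain_classified(self, tmp_path):
        path = write_pdb(tmp_path / "3ccc.pdb", [("A", DNA22, "C1'", ())])
        (rec,) = parse_structure(path, pdb_id="3CCC")
        assert rec.polymer_class == "DNA"

    def test_unresolved_residues_flagged_and_seqres_wins(self, tmp_path):
        path = write_pdb(tmp_path / "4ddd.pdb", [("A", RNA25, "C1'", (10, 11))])
        (rec,) = parse_structure(path, pdb_id="4DDD")
        assert rec.has_unresolved_residues
        assert rec.length == 25  # full SEQRES length, not observed count
        assert rec.sequence == "".join(RNA25)

    def test_modified_residues_normalized_in_sequence(self, tmp_path):
        codes = list("ACGU") * 5 + ["PSU", "5MC", "1MA", "OMG", "XYZ"]
        path = write_pdb(tmp_path / "5eee.pdb", [("A", codes, "C1'", ())])
        (rec,) = parse_structure(path, pdb_id="5EEE")
        assert rec.sequence.endswith("UCAGN")
        assert rec.polymer_class == "RNA"

    def test_zero_polymer_chains_yields_empty(self, tmp_path):
        path = tmp_path / "6fff.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00"
            "           O\nEND\n"
        )
        assert parse_structure(path, pdb_id="6FFF") == []

    def test_unreadable_file_raises_parse_error(self, tmp_path):
        with pytest.raises((StructureParseError, FileNotFoundError)):
            parse_structure(tmp_path / "missing.pdb", pdb_id="0XXX")

    def test_minimal_mmcif_dialect(self, tmp_path):
        path = tmp_path / "7ggg.cif"
        rows = "\n".join(
            f"ATOM {i + 1} C \"C1'\" . {c} A 1 {i + 1} ? {3.0 * i:.3f} 0.000 0.000 1.00 0.00 {i + 1} {c} A C1 1"
            for i, c in enumerate(RNA25)
        )
        path.write_text(f"""data_7GGG
loop_
_entity_poly_seq.entity_id
_entity_poly_seq.num
_entity_poly_seq.mon_id
{chr(10).join(f'1 {i + 1} {c}' for i, c in enumerate(RNA25))}
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.auth_atom_id
_atom_site.pdbx_PDB_model_num
{rows}
""")
        (rec,) = parse_structure(path, pdb_id="7GGG")
        assert rec.polymer_class == "RNA" and rec.length == 25


class TestNormalizeResidue:
    @pytest.mark.parametrize(
        "code,expected",
        [("G", "G"), ("a", "A"), ("U", "U"), ("PSU", "U"), ("5MC", "C"),
         ("1MA", "A"), ("7MG", "G"), ("XXX", "N"), ("N", "N"), ("DA", "N")],
    )
    def test_mapping(self, code, expected):
        assert normalize_residue(code) == expected

    def test_user_extension_overrides(self, tmp_path):
        extra = tmp_path / "extra.tsv"
        extra.write_text("ZZZ\tG\n")
        table = load_parent_table(extra)
        assert normalize_residue("ZZZ", table) == "G"

    @given(st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789", min_size=1, max_size=3))
    def test_total_with_nucleotide_image(self, code):
        assert normalize_residue(code) in set("ACGUN")


class TestClassifyPolymer:
    @pytest.mark.parametrize(
        "codes,expected",
        [(["A", "U", "G", "C"], "RNA"),
         (["DA", "DC", "DG"], "DNA"),
         (["A", "DA", "U"], "hybrid"),
         (["ALA", "GLY"], "protein"),
         (["A", "PSU", "N"], "RNA"),
         (["A", "ALA"], "other"),
         (["XXX", "YYY"], "other")],
    )
    def test_classification(self, codes, expected):
        assert classify_polymer(codes) == expected

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            classify_polymer([])


def chain(length=25, cls="RNA", n_count=0, unresolved=False, cid="A"):
    seq = ("ACGU" * (length // 4 + 1))[:length]
    if n_count:
        seq = "N" * n_count + seq[n_count:]
    return ChainRecord(pdb_id="1AAA", chain_id=cid, polymer_class=cls,
                       sequence=seq, length=length,
                       has_unresolved_residues=unresolved)


class TestFilterChains:
    @pytest.mark.parametrize(
        "record,reason",
        [(chain(length=19), "length"),
         (chain(cls="DNA"), "polymer_class"),
         (chain(length=30, n_count=10), "unknown_fraction")],
    )
    def test_removal_reasons(self, record, reason):
        kept, removed = filter_chains([record], ChainFilterConfig(min_length=20))
        assert kept == [] and removed == [(record.label, reason)]

    def test_boundary_length_is_kept(self):
        kept, _ = filter_chains([chain(length=20)], ChainFilterConfig(min_length=20))
        assert len(kept) == 1

    def test_unresolved_only_removed_when_required(self):
        rec = chain(unresolved=True)
        kept, _ = filter_chains([rec], ChainFilterConfig())
        assert kept == [rec]
        _, removed = filter_chains([rec], ChainFilterConfig(require_no_unresolved=True))
        assert removed == [(rec.label, "unresolved")]

    @given(st.lists(st.tuples(st.integers(1, 40), st.sampled_from(["RNA", "DNA", "protein"]),
                              st.integers(0, 10)), max_size=15))
    def test_conservation_and_idempotence(self, plans):
        chains = [chain(length=ln, cls=cls, n_count=min(nc, ln), cid=chr(65 + i % 26))
                  for i, (ln, cls, nc) in enumerate(plans)]
        cfg = ChainFilterConfig()
        kept, removed = filter_chains(chains, cfg)
        assert len(kept) + len(removed) == len(chains)
        kept2, removed2 = filter_chains(kept, cfg)
        assert kept2 == kept and removed2 == []
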