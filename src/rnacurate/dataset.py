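"""The output unit of a curation run: one RNA chain with its provenance."""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class DatasetEntry:
    """One curated RNA chain.

    Carries the chain sequence plus the entry-level attributes users need
    downstream (resolution, method, year, how many polymer chains the source
    entry had) and, when annotation ran, the assigned Rfam family with its
    E-value and bit score.
    """

    pdb_id: str
    chain_id: str
    sequence: str
    length: int
    resolution: float | None
    experimental_method: str
    release_year: int
    n_chains_in_entry: int
    rfam_accession: str | None = None
    rfam_e_value: float | None = None
    rfam_bit_score: float | None = None

    @property
    def label(self) -> str:
        return f"{self.pdb_id}_{self.chain_id}"

    def with_hit(self, accession: str, e_value: float, bit_score: float) -> "DatasetEntry":
        return replace(
            self, rfam_accession=accession, rfam_e_value=e_value, rfam_bit_score=bit_score
        )


#: fixed column order of the dataset TSV
DATASET_COLUMNS = (
    "pdb_id",
    "chain_id",
    "sequence",
    "length",
    "resolution",
    "experimental_method",
    "release_year",
    "n_chains_in_entry",
    "rfam_accession",
    "rfam_e_value",
    "rfam_bit_score",
)
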