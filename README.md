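# rnacurate

Curation of **non-redundant, quality-controlled RNA chain datasets** from
PDB-style structure catalogs.

Experimentally determined RNA structures are scarce, and what exists in the
PDB is highly redundant (many near-identical deposits of the same
molecule), of uneven quality (coarse resolutions, hybrid protein/RNA and
DNA/RNA complexes), and cluttered with very short fragments. Anyone
training or benchmarking an RNA structure-prediction model needs a
filtered, deduplicated chain set — and needs the filtering to be explicit
and reproducible, because redundancy and train/test leakage directly
inflate reported performance. `rnacurate` automates that curation as a
deterministic pipeline over pinned, offline inputs.

## The pipeline

Four stages run in a fixed order, cheap filters first, and each reports
input / retained / removed counts:

1. **Metadata filter** (entry level) — experimental method, resolution
   strictly below a threshold (in Å; entries without a resolution, e.g.
   NMR, fail unless explicitly allowed), release year (before-year
   exclusive, or an inclusive range), polymer entity types, case-insensitive
   keyword terms, RNA subtypes.
2. **Chain filter** (instance level) — coordinate files (PDB or mmCIF,
   parsed with gemmi) are split into polymer chains; each chain is
   classified (RNA / DNA / protein / hybrid / other) from its residue
   codes, modified ribonucleotides are mapped to parent bases (e.g.
   PSU → U) via a bundled, user-extensible table, and chains are kept only
   if they match the target class, reach the minimum length (default 20
   residues, inclusive), and stay below the unknown-residue bound.
3. **Sequence-identity redundancy removal** — all-vs-all percent identity
   `SI = 100 · identical columns / alignment length` from optimal global
   alignments under affine gap penalties (needle-style nucleotide scoring:
   match +5, mismatch −4, gap open 10, gap extend 0.5). Chains are ranked
   best resolution first and kept greedily unless their SI to an already
   kept chain strictly exceeds the threshold (default 50 %), so every
   redundant group is represented by its best-resolved member.
4. **Rfam family annotation and deduplication** — Infernal
   `cmscan --tblout` output (precomputed, or run via the provided wrapper)
   assigns each chain its best covariance-model hit (smallest E-value);
   within each Rfam family only the lowest-E-value chain survives. Chains
   without a significant hit (default E ≤ 0.01) are kept unannotated.

Outputs: a TSV chain table (sequence, length, resolution, method, year,
chains in source entry, Rfam accession/E-value/bit score), a FASTA export,
and a machine-readable JSON stage report. Identical inputs give
byte-identical outputs.

## Worked example

The package ships a synthetic-corpus generator with planted ground truth
(`rnacurate fixtures`), which is also how the pipeline is tested offline:

```console
$ rnacurate fixtures --seed 11 --out-dir demo
$ rnacurate build --catalog demo/catalog.jsonl --structures demo/structures \
    --tblout-file demo/hits.tblout --method "X-RAY DIFFRACTION" \
    --max-resolution 3.6 --min-length 20 --si-threshold 50 --out demo/dataset.tsv
metadata       entries  in=3     kept=2     removed=1     (0.00s)
chain_filter   chains   in=6     kept=5     removed=1     (0.00s)
si_redundancy  chains   in=5     kept=5     removed=0     (0.00s)
rfam_dedup     chains   in=5     kept=3     removed=2     (0.00s)
final dataset: 3 chains -> demo/dataset.tsv
```

Reading the report: of 3 catalog entries one fails the metadata filter
(here: resolution not below 3.6 Å); the 2 surviving entries contain 6
polymer chains of which one fails the chain filter; no pair of the 5
remaining chains exceeds 50 % sequence identity, so none is removed as
redundant; two chains share Rfam families with better-scoring chains and
are dropped, leaving 3 curated chains. The table starts:

```
pdb_id  chain_id  sequence              length  resolution  ...  rfam_accession  rfam_e_value
1F00    C         UCCCGGGCCACAUGCUAUG…  38      2.7         ...
3F02    B         ACGACGCUCUCGCAAUCCC…  49      2.47        ...  RF10000         0.00011574407653429439
3F02    C         CGGCAGAGCGAAAAUAAUA…  30      2.47        ...  RF10001         9.001902748760027e-11
```

Every stage is also available standalone (`filter-meta`, `filter-chains`,
`reduce`, `annotate`), e.g. `rnacurate reduce --fasta seqs.fa
--si-threshold 50` prints a non-redundant representative list. The same
functionality is importable as a library (`rnacurate.build_dataset`,
`rnacurate.pairwise_identity`, …). A catalog can be built offline from
JSON-lines (one entry per line, fields `pdb_id`, `experimental_method`,
`resolution`, `release_year`, `polymer_entity_types`, `keywords`,
`rna_subtypes`; unknown fields ignored) or fetched live from the RCSB
search + GraphQL endpoints through an injectable adapter.

## Scope

The curation logic is fully self-contained and offline-testable. Running
Infernal itself, live RCSB retrieval, and any structure-prediction
evaluation built on top of the curated sets are outside the package's
scope; `cmscan` output is consumed via `--tblout-file`, and the live
catalog adapter is an isolated, injectable boundary.
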