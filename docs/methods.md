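# Methods

This note documents the models, conventions and numerical choices behind
`rnacurate`, and what its synthetic-corpus tests do and do not establish.

## Sequence identity

Percent sequence identity (SI) between two RNA chains is defined from an
optimal **global** alignment under affine gap penalties:

    SI = 100 · (identical aligned columns) / (alignment length, gaps included)

Scoring defaults follow the EMBOSS needle nucleotide scheme: match +5,
mismatch −4, gap open 10, gap extend 0.5, with a gap of length *k* costing
`open + (k−1)·extend` and end gaps penalized like any other gap. The
denominator includes gap columns, which is the conservative choice for
redundancy screening (a short fragment of a long chain does not score as
near-identical); the alternative (shorter-sequence denominator) can be
obtained by scaling but is not built in. The unknown residue `N` never
counts as identical — not even to itself — and scores as a mismatch, so
low-quality chains cannot cluster on shared ambiguity.

**Well-definedness.** Optimal-score alignments are generally not unique,
and different optima can have different identity counts. SI is therefore
defined by a lexicographic objective: maximize score, then identical
columns, then minimize alignment length. This is computed exactly by
running Biopython's `PairwiseAligner` (Gotoh algorithm, C implementation)
on a composite integer scoring that encodes the three-level objective in
one scalar: with `B2 = m+n+1` and `B1 = 2·B2·(min(m,n)+2)`, each aligned
column contributes `B1·(2·score) + B2·[identical] − 1`, and gaps
analogously; score, identities and length are recovered from the single
optimal value by exact integer decomposition. Scores are pre-scaled to
integers (arbitrary rational parameters are supported via their common
denominator), and an overflow guard rejects inputs whose composite bound
would exceed exact double-precision range (far beyond any realistic chain
length at the default parameters). The test suite checks this engine —
score, identity count and alignment length, i.e. including tie-breaking —
against an independent exhaustive enumeration of *every* global alignment,
exhaustively for all sequence pairs up to length 4 and on >10,000 sampled
pairs up to length 6 with Ns.

## Redundancy removal

Chains are ranked by: resolution ascending (absent resolutions — NMR —
last), then release year ascending, then label. Scanning in rank order, a
chain is kept iff its SI to every already-kept chain does not exceed the
threshold; "exceeds" is strict, so SI exactly at the threshold (default
50 %) is kept. The result is deterministic, O(n²), maximal (every removed
chain exceeds the threshold against the kept chain recorded as displacing
it), and implements the keep-the-better-resolution rule on every pair it
resolves.

Greedy selection was chosen over exact maximum-independent-set because the
pairwise preference rule does not define a unique globally optimal set
when similarity is intransitive, and the greedy is the deterministic,
auditable closure of that rule. One consequence is documented and tested
honestly rather than hidden: **the number of kept chains is not monotone
in the threshold.** Relaxing the threshold can free a high-ranked chain
that then displaces several chains the stricter run kept (ranks 1<2<3<4
with SI(1,2)=55, SI(2,3)=SI(2,4)=80: threshold 50 keeps three chains,
threshold 60 keeps two). The dedicated monotonicity test in the acceptance
suite fails for exactly this reason, verifies via the independent oracle
that the shrinkage is a property of the rule itself, and is retained as a
known limitation. An exact independent-set formulation would be monotone
but would sacrifice the simple rank-order semantics.

## Filters

* Resolution: strict `<` ("below" a threshold). Entries without a
  resolution fail an active resolution filter unless
  `allow_missing_resolution` is set, so unquantified-quality entries never
  pass silently.
* Years: `year_before` exclusive; `year_range` inclusive at both ends.
* Keywords: case-insensitive substring match on the free-text keyword
  field; any configured include-term suffices, any exclude-term removes.
* Removal reasons name the first failing predicate in the fixed order
  method → resolution → year → entity types → keywords → subtypes.
* Chain length: inclusive minimum, default 20 residues — the conventional
  cut below which RNA chains are uninformative fragments. Length counts
  the full polymer sequence record (SEQRES/`entity_poly`) when present,
  including unresolved residues.
* Sequence source: the full polymer sequence record takes precedence over
  observed residues, because redundancy should be judged on the full
  construct; disagreement between the two (or gaps in observed numbering)
  sets `has_unresolved_residues`, which filters chains only when
  `require_no_unresolved` is requested. This operationalizes "residue
  integrity" as unresolved-residue detection plus an unknown-fraction
  bound (default ≤ 0.1 of residues mapping to `N`).
* Polymer classification: residue codes are classed as ribo- or
  deoxyribonucleotide, amino acid, or unknown; unknown codes are
  class-neutral (they become `N` in the sequence, bounded by the
  unknown-fraction filter). Ribo+deoxy mixtures are `hybrid`;
  nucleotide+amino mixtures fall to `other`. Multi-model (NMR) files use
  the first model only.

## Rfam annotation

A chain's family is its best `cmscan` hit: smallest E-value, ties by
larger bit score, then accession. Hits above the E-value threshold
(default 0.01 — a conventional significance cut; the tool that produced
the tblout governs the statistics) leave the chain unannotated but
retained; `require_family` flips that. Family dedup keeps, per accession,
the chain with the smallest E-value (ties: bit score, then resolution,
then label). Dedup runs after SI-based redundancy removal, as a second,
annotation-level redundancy pass. Clan competition and covariance-model
construction are out of scope.

## Synthetic corpora and what the tests show

All end-to-end testing uses generated corpora with planted truth, because
real PDB snapshots are dated, large, and irreproducible as fixtures. The
generator plants: entries that fail each metadata predicate, chains that
fail each chain predicate, redundancy groups (point-mutated copies of a
group seed at 8 % substitution rate, no indels, so within-group SI stays
high and analytically predictable), independent random sequences across
groups, and shared Rfam families with chosen E-values written as a
`cmscan --tblout` file. Planted SI structure is verified post hoc with
the package's own `pairwise_identity` — which the exhaustive-alignment
oracle validates separately at small lengths — and offending sequences are
redrawn; an unrealizable plan (e.g. a redundancy group at threshold 100)
raises rather than producing a silently wrong corpus.

Expected outcomes are computed by `replay_truth`, a second, independent
implementation of the documented rules that never touches the pipeline
code path; pipeline output must match it exactly (survivors, per-stage
counts, removal reasons, annotations) on 100+ randomized corpora of up to
15 entries. Sizes were chosen so the whole suite runs in well under a
minute of alignment time while still exercising every stage interaction
(e.g. a redundancy-group loser carrying the only hit of a family).

These corpora deliberately do **not** emulate: realistic 3D geometry
(coordinates are placeholder traces; no geometry validation exists to
exercise), indels within redundancy groups (optional in principle, off by
default to keep planted SI analytic), multi-model ensembles beyond
first-model collapse, assembly/symmetry expansion, or the true length and
family distributions of the PDB. Passing tests therefore establish the
correctness of the filtering, alignment, selection and accounting logic —
not calibration against any particular PDB snapshot, whose counts depend
on retrieval date and on external Infernal runs.

## Reporting

Each run emits an ordered stage report (input, retained, removed, elapsed
seconds per stage). Counts partition exactly at every stage and chain
across consecutive stages that share a unit; the first two stages count
different units (entries, then chains), which the report makes explicit
with a `unit` field. The machine-readable JSON report contains the counts,
the redundancy displacement list `(removed, kept, SI%)` and all removal
reasons, but not timings — timings go to the log — so that identical
inputs yield byte-identical TSV, FASTA and JSON outputs; this determinism
is asserted by the tests and measured by the acceptance script.
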