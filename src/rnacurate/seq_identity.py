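"""Pairwise percent sequence identity (SI) by global alignment.

SI between two RNA sequences is defined from an optimal global alignment
under affine gap penalties (needle-style nucleotide scoring by default:
match +5, mismatch -4, gap open 10, gap extend 0.5, a gap of length k
costing ``open + (k-1)*extend``, end gaps penalized):

    SI = 100 * (identical aligned columns) / (alignment length incl. gaps)

Optimal-score alignments are not unique, so the reported identity is made
well-defined by a lexicographic objective: maximize alignment score, then
the number of identical columns, then minimize alignment length.  The
``N`` (unknown) residue never counts as identical, not even against itself,
and scores as a mismatch.

The engine is Bio.Align.PairwiseAligner (Gotoh, C speed) run on a composite
integer scoring that encodes the lexicographic objective in a single
scalar; score, identities and alignment length are then recovered exactly
by arithmetic decomposition, without extracting an alignment.  Adapters for
external aligners (Clustal Omega, EMBOSS needle) can be layered on top but
are not required: the computation is fully defined here.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from typing import NamedTuple, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentParams",
    "AlignmentStats",
    "SIMatrix",
    "pairwise_identity",
    "alignment_stats",
    "build_si_matrix",
    "cross_dataset_similarity",
    "si_bin",
]

ALPHABET = "ACGUN"
_ALPHASET = frozenset(ALPHABET)


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap nucleotide scoring; defaults follow the EMBOSS needle
    DNA/RNA scheme (EDNAFULL match/mismatch with default gap penalties)."""

    match_score: float = 5.0
    mismatch_score: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")
        if not self.match_score > self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")


class AlignmentStats(NamedTuple):
    score: float
    identities: int
    length: int

    @property
    def identity(self) -> float:
        return 100.0 * self.identities / self.length


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} is empty")
    bad = set(seq) - _ALPHASET
    if bad:
        raise ValueError(f"{name} contains non-RNA characters {sorted(bad)}")


def _integer_scores(params: AlignmentParams) -> tuple[int, int, int, int, int]:
    """Scale (match, mismatch, open, extend) to exact integers."""
    fracs = [
        Fraction(x).limit_denominator(10**6)
        for x in (params.match_score, params.mismatch_score, params.gap_open, params.gap_extend)
    ]
    den = 1
    for f in fracs:
        den = den * f.denominator // gcd(den, f.denominator)
    return tuple(int(f * den) for f in fracs) + (den,)  # type: ignore[return-value]


def alignment_stats(seq_a: str, seq_b: str, params: AlignmentParams | None = None) -> AlignmentStats:
    """Score, identical columns and alignment length of the lexicographically
    optimal global alignment (max score, then max identities, then min length)."""
    params = params or AlignmentParams()
    _check_sequence(seq_a, "seq_a")
    _check_sequence(seq_b, "seq_b")
    m, n = len(seq_a), len(seq_b)
    match_i, mism_i, open_i, ext_i, den = _integer_scores(params)

    # Composite column scoring: C = B1 * scaled_score + B2 * identities - length.
    # B2 dominates length (length <= m+n < B2); B1 dominates the identity/length
    # band (|B2*I - L| < B1/2), so C decomposes uniquely.
    B2 = m + n + 1
    B1 = 2 * B2 * (min(m, n) + 2)
    bound = B1 * (abs(match_i) + abs(mism_i) + abs(open_i) + abs(ext_i) + 1) * (m + n + 2)
    if bound > 2**52:
        raise OverflowError("sequences too long for exact composite scoring")

    mat = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for x in ALPHABET:
        for y in ALPHABET:
            if x == y and x != "N":
                mat[x, y] = match_i * B1 + B2 - 1
            else:
                mat[x, y] = mism_i * B1 - 1
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    # first gap column costs the full open penalty, later columns extend
    aligner.open_gap_score = -(open_i * B1 + 1)
    aligner.extend_gap_score = -(ext_i * B1 + 1)

    composite = int(round(aligner.score(seq_a, seq_b)))
    scaled, rem = _round_div(composite, B1)
    identities = -((-rem) // B2)  # ceil(rem / B2)
    length = B2 * identities - rem
    return AlignmentStats(score=scaled / den, identities=identities, length=length)


def _round_div(value: int, divisor: int) -> tuple[int, int]:
    """Nearest-integer division with remainder in (-divisor/2, divisor/2]."""
    q = (2 * value + divisor) // (2 * divisor)
    return q, value - q * divisor


def pairwise_identity(seq_a: str, seq_b: str, params: AlignmentParams | None = None) -> float:
    """Percent identity in [0, 100]; symmetric in its arguments."""
    return alignment_stats(seq_a, seq_b, params).identity


# --- SI matrix -------------------------------------------------------------


@dataclass(frozen=True)
class SIMatrix:
    """Symmetric all-vs-all percent-identity matrix with chain labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


def _label_seq(item) -> tuple[str, str]:
    if hasattr(item, "label") and hasattr(item, "sequence"):
        return item.label, item.sequence
    label, seq = item
    return label, seq


def build_si_matrix(chains: Sequence, params: AlignmentParams | None = None) -> SIMatrix:
    """All-vs-all SI over chains (ChainRecords or ``(label, sequence)`` pairs).

    Only the upper triangle is aligned; values are mirrored and the diagonal
    is 100 by definition.
    """
    pairs = [_label_seq(c) for c in chains]
    if not pairs:
        raise ValueError("need at least one chain")
    n = len(pairs)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            si = pairwise_identity(pairs[i][1], pairs[j][1], params)
            values[i, j] = values[j, i] = si
    return SIMatrix(labels=tuple(lab for lab, _ in pairs), values=values)


# --- cross-dataset subclassing --------------------------------------------


def si_bin(identity: float) -> str:
    """Similarity subclass: ``low`` (<=50), ``mid`` ((50, 75]), ``high`` (>75)."""
    if identity <= 50.0:
        return "low"
    if identity <= 75.0:
        return "mid"
    return "high"


class CrossMatch(NamedTuple):
    query: str
    max_identity: float
    closest_reference: str
    bin: str


def cross_dataset_similarity(
    query_chains: Sequence,
    reference_chains: Sequence,
    params: AlignmentParams | None = None,
) -> list[CrossMatch]:
    """For each query chain, the maximum SI against a reference set.

    Used to subclass the chains of a new dataset by similarity to an older
    one (e.g. to stratify prediction benchmarks by training-set overlap).
    Ties on the maximum go to the lexicographically smallest reference id.
    """
    queries = [_label_seq(c) for c in query_chains]
    refs = [_label_seq(c) for c in reference_chains]
    if not queries:
        raise ValueError("empty query set")
    if not refs:
        raise ValueError("empty reference set")
    out: list[CrossMatch] = []
    for qlabel, qseq in queries:
        best_si, best_ref = -1.0, ""
        for rlabel, rseq in sorted(refs):
            si = pairwise_identity(qseq, rseq, params)
            if si > best_si:
                best_si, best_ref = si, rlabel
        out.append(CrossMatch(qlabel, best_si, best_ref, si_bin(best_si)))
    return out
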