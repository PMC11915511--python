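"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the alignment oracle
enumerates every global alignment recursively; the representative-selection
oracle re-derives the greedy rule by repeated exhaustive scanning.
"""

from __future__ import annotations

import math


def brute_force_alignment(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[float, int, int]:
    """Enumerate all global alignments of *a* and *b*.

    Returns (score, identities, length) of the alignment maximizing
    (score, identities, -length) lexicographically.  A gap of length k costs
    gap_open + (k-1)*gap_extend; end gaps are penalized; 'N' never counts as
    identical and scores as a mismatch.  Exponential: lengths <= ~8 only.
    """
    m, n = len(a), len(b)
    best: list[tuple[float, int, int] | None] = [None]

    def rec(i: int, j: int, score: float, ident: int, length: int, prev: int) -> None:
        if i == m and j == n:
            key = (score, ident, -length)
            if best[0] is None or key > best[0]:
                best[0] = key
            return
        if i < m and j < n:
            eq = a[i] == b[j] and a[i] != "N"
            rec(i + 1, j + 1, score + (match if eq else mismatch),
                ident + (1 if eq else 0), length + 1, 0)
        if i < m:
            rec(i + 1, j, score - (gap_extend if prev == 1 else gap_open),
                ident, length + 1, 1)
        if j < n:
            rec(i, j + 1, score - (gap_extend if prev == 2 else gap_open),
                ident, length + 1, 2)

    rec(0, 0, 0.0, 0, 0, -1)
    score, ident, neglen = best[0]  # type: ignore[misc]
    return score, ident, -neglen


def brute_force_identity(a: str, b: str, **kwargs) -> float:
    score, ident, length = brute_force_alignment(a, b, **kwargs)
    return 100.0 * ident / length


def greedy_representatives_oracle(labels, si, attrs, threshold):
    """Re-derivation of representative selection by exhaustive scanning.

    labels: sequence of ids; si: dict[(i, j)] -> percent for every unordered
    pair; attrs: dict id -> (resolution or None, year, id).  At each step the
    best remaining candidate (smallest resolution, missing last; then year;
    then id) is kept and every remaining label with SI strictly above the
    threshold to it is discarded.
    """

    def rank(lab):
        res, year, _ = attrs[lab]
        return (res is None, res if res is not None else math.inf,
                year if year is not None else math.inf, lab)

    remaining = set(labels)
    kept = []
    removed = {}
    while remaining:
        pick = min(remaining, key=rank)
        kept.append(pick)
        remaining.discard(pick)
        for other in sorted(remaining):
            pair = (pick, other) if (pick, other) in si else (other, pick)
            if si[pair] > threshold:
                remaining.discard(other)
                removed[other] = pick
    return sorted(kept), removed
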