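"""Non-redundant representative selection from an SI matrix.

Greedy best-quality-first selection: candidates are ranked by resolution
(smaller Å is better; chains without a resolution, typically NMR, rank
last), then earlier release year, then lexicographic id.  Scanning in that
order, a candidate is kept iff its SI to every already-kept label does not
exceed the threshold — "exceeds" is strict, so SI exactly equal to the
threshold does not trigger removal.  The result is a maximal set: no kept
pair is above the threshold, and every removed label is above the threshold
to at least one kept label (the one recorded as displacing it).

The greedy is deterministic and O(n^2); it implements the pairwise
keep-the-better-resolution rule exactly on every pair it resolves, without
attempting an exact maximum-independent-set optimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

from .seq_identity import SIMatrix

__all__ = ["RedundancyConfig", "LabelAttrs", "Removal", "select_representatives"]


@dataclass(frozen=True)
class RedundancyConfig:
    """``si_threshold`` is a percent in (0, 100]; 50 mirrors the common
    "maximum pairwise SI of 50%" curation setting."""

    si_threshold: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 < self.si_threshold <= 100.0:
            raise ValueError("si_threshold must be in (0, 100]")


class LabelAttrs(NamedTuple):
    resolution: float | None
    release_year: int | None
    label: str


class Removal(NamedTuple):
    removed: str
    kept: str
    identity: float


def _rank(attrs: LabelAttrs) -> tuple:
    return (
        attrs.resolution is None,
        attrs.resolution if attrs.resolution is not None else math.inf,
        attrs.release_year if attrs.release_year is not None else math.inf,
        attrs.label,
    )


def select_representatives(
    matrix: SIMatrix,
    attributes: Mapping[str, LabelAttrs],
    config: RedundancyConfig | None = None,
) -> tuple[list[str], list[Removal]]:
    """Greedy representative selection; see module docstring for the rule.

    Returns kept labels (in matrix label order) and, for each removed label,
    the kept label that displaced it together with their SI.

    Raises
    ------
    ValueError
        If the matrix labels and attribute keys do not coincide.
    """
    config = config or RedundancyConfig()
    labels = list(matrix.labels)
    if set(labels) != set(attributes):
        raise ValueError("matrix labels and attribute keys do not coincide")
    index = {lab: i for i, lab in enumerate(labels)}
    order = sorted(labels, key=lambda lab: _rank(attributes[lab]))
    kept: list[str] = []
    removals: list[Removal] = []
    for cand in order:
        displaced_by = None
        for k in kept:
            si = float(matrix.values[index[cand], index[k]])
            if si > config.si_threshold:
                displaced_by = (k, si)
                break
        if displaced_by is None:
            kept.append(cand)
        else:
            removals.append(Removal(cand, displaced_by[0], displaced_by[1]))
    kept_in_matrix_order = [lab for lab in labels if lab in set(kept)]
    removals.sort(key=lambda r: r.removed)
    return kept_in_matrix_order, removals
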