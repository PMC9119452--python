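"""Kimura 2-parameter distances and within/between-group summaries.

The K2P distance corrects observed differences for multiple hits, treating
transitions (A<->G, C<->T; proportion P) and transversions (proportion Q)
separately:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites where either sequence carries a gap or ambiguity code are excluded
pairwise ("pairwise deletion"). When a log argument is non-positive the pair
is saturated: it is flagged, never clipped, and excluded from group means.

Group summaries are unweighted means over haplotype pairs — haplotype
frequencies never enter — matching the convention of averaging pairwise
haplotype distances within and between taxa. The barcoding gap compares the
pooled range of within-species distances against the pooled between-species
range; a usable barcode locus shows no overlap.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_TS_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class PairwiseDistance:
    """K2P distance between two aligned sequences.

    ``d`` is NaN when the pair is saturated (1-2P-Q <= 0 or 1-2Q <= 0).
    """

    d: float
    P: float
    Q: float
    n_sites: int
    saturated: bool = False


@dataclass
class GroupSummary:
    """Mean/min/max pairwise distance within (group_a == group_b) or between groups."""

    group_a: str
    group_b: str
    mean: float
    min: float
    max: float
    n_pairs: int

    @property
    def within(self) -> bool:
        return self.group_a == self.group_b


@dataclass
class GapReport:
    """Pooled within- vs between-species distance ranges and their separation."""

    within_range: tuple[float, float]
    between_range: tuple[float, float]
    overlap: bool
    fold_ratio: float


def k2p(seq1: str, seq2: str) -> PairwiseDistance:
    """K2P distance between two equal-length sequences with pairwise deletion."""
    if len(seq1) != len(seq2):
        raise ValueError(
            f"sequence lengths differ: {len(seq1)} vs {len(seq2)}"
        )
    n = ts = tv = 0
    for a, b in zip(seq1, seq2):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a != b:
            if (a, b) in _TS_PAIRS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    P, Q = ts / n, tv / n
    arg1, arg2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return PairwiseDistance(d=math.nan, P=P, Q=Q, n_sites=n, saturated=True)
    d = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    return PairwiseDistance(d=d, P=P, Q=Q, n_sites=n)


class DistanceMatrix:
    """Symmetric K2P distance matrix over named haplotypes.

    ``values[i, j]`` is NaN where the pair is saturated; ``saturated`` is the
    matching boolean mask. The diagonal is exactly zero.
    """

    def __init__(self, labels: Sequence[str], values: np.ndarray,
                 saturated: np.ndarray):
        labels = list(labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in distance matrix")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match labels")
        self.labels = labels
        self.values = values
        self.saturated = np.asarray(saturated, dtype=bool)
        self._index = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def is_saturated(self, a: str, b: str) -> bool:
        return bool(self.saturated[self._index[a], self._index[b]])

    @property
    def any_saturated(self) -> bool:
        return bool(self.saturated.any())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[lab] for lab in labels]
        return DistanceMatrix(
            [self.labels[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.saturated[np.ix_(idx, idx)],
        )


def distance_matrix(haplotypes: Iterable) -> DistanceMatrix:
    """All-pairs K2P matrix over haplotypes (objects with .name and .sequence,
    or (name, sequence) tuples)."""
    named = []
    for h in haplotypes:
        if isinstance(h, tuple):
            named.append(h)
        else:
            named.append((h.name, h.sequence))
    if len(named) < 2:
        raise ValueError("need at least 2 haplotypes")
    labels = [n for n, _ in named]
    n = len(named)
    values = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        pw = k2p(named[i][1], named[j][1])
        values[i, j] = values[j, i] = pw.d
        if pw.saturated:
            saturated[i, j] = saturated[j, i] = True
            logger.warning(
                "saturated pair %s / %s (P=%.3f, Q=%.3f); excluded from means",
                labels[i], labels[j], pw.P, pw.Q,
            )
    return DistanceMatrix(labels, values, saturated)


def _summary(group_a: str, group_b: str, dists: list[float]) -> GroupSummary:
    if not dists:
        return GroupSummary(group_a, group_b, 0.0, 0.0, 0.0, 0)
    return GroupSummary(
        group_a, group_b,
        mean=float(np.mean(dists)), min=float(np.min(dists)),
        max=float(np.max(dists)), n_pairs=len(dists),
    )


def group_summaries(
    matrix: DistanceMatrix,
    group_map: Mapping[str, str],
    exclude: frozenset | set = frozenset(),
) -> list[GroupSummary]:
    """Within- and between-group distance summaries, unweighted over pairs.

    Every matrix label must be mapped by ``group_map`` or listed in
    ``exclude`` (the hybrid-suspect exclusion). Saturated pairs are skipped.
    A single-haplotype group reports within mean=min=max=0 with n_pairs=0.
    """
    unmapped = [
        lab for lab in matrix.labels if lab not in group_map and lab not in exclude
    ]
    if unmapped:
        raise ValueError(f"unmapped matrix label(s): {unmapped}")
    members: dict[str, list[str]] = {}
    for lab in matrix.labels:
        if lab in exclude:
            continue
        members.setdefault(group_map[lab], []).append(lab)

    summaries = []
    groups = list(members)
    for g in groups:
        dists = [
            matrix.get(a, b)
            for a, b in itertools.combinations(members[g], 2)
            if not matrix.is_saturated(a, b)
        ]
        summaries.append(_summary(g, g, dists))
    for ga, gb in itertools.combinations(groups, 2):
        dists = [
            matrix.get(a, b)
            for a in members[ga]
            for b in members[gb]
            if not matrix.is_saturated(a, b)
        ]
        summaries.append(_summary(ga, gb, dists))
    return summaries


def barcode_gap(
    within: Sequence[GroupSummary], between: Sequence[GroupSummary]
) -> GapReport:
    """Pool within/between summaries into a barcoding-gap report.

    ``fold_ratio`` is the mean of between-group means over the mean of
    within-group means (infinity when the latter is zero).
    """
    if not within or not between:
        raise ValueError("need at least one within and one between summary")
    w_lo = min(s.min for s in within)
    w_hi = max(s.max for s in within)
    b_lo = min(s.min for s in between)
    b_hi = max(s.max for s in between)
    w_mean = float(np.mean([s.mean for s in within]))
    b_mean = float(np.mean([s.mean for s in between]))
    return GapReport(
        within_range=(w_lo, w_hi),
        between_range=(b_lo, b_hi),
        overlap=b_lo <= w_hi,
        fold_ratio=(b_mean / w_mean) if w_mean > 0 else math.inf,
    )


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Tabulate summaries with 4-decimal rounding (report convention)."""
    return pd.DataFrame(
        [
            {
                "group_a": s.group_a,
                "group_b": s.group_b,
                "mean": round(s.mean, 4),
                "min": round(s.min, 4),
                "max": round(s.max, 4),
                "n_pairs": s.n_pairs,
            }
            for s in summaries
        ]
    )
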