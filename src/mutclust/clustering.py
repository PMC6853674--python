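"""Cluster identification on a smoothing curve.

Clusters seed at local maxima of the curve and extend to the flanking local
minima; nearby clusters (raw peaks within the cluster window of each other)
are merged, and clusters supported by too few mutations are discarded.

Definitions used throughout (chosen so results are deterministic and the
surviving clusters never overlap):

* A plateau of equal values is a single extremum represented by its
  *leftmost* index.
* Raw cluster spans partition ``[0, L)``: the minimum plateau separating two
  consecutive peaks is split at its midpoint (left half to the left cluster),
  and the outermost clusters run to the element edges.
* Merging takes the transitive closure of "consecutive raw peaks within
  ``w_cluster`` of each other"; the merged peak is the member peak with the
  largest smoothing value (leftmost on ties).
* Curve values are compared after rounding to 1e-10 so plateau detection does
  not depend on floating-point summation order.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

_ROUND_DECIMALS = 10

#: raw span: (left, right, peak, peak height), indices inclusive
Span = tuple[int, int, int, float]


@dataclass
class Cluster:
    """A contiguous run of element positions around a smoothing maximum."""

    left: int
    right: int
    peak: int
    positions: dict[int, int] = field(default_factory=dict)  # index -> mutation count
    peak_height: float = 0.0
    element_id: Optional[str] = None
    score: Optional[float] = None
    p_value: Optional[float] = None

    @property
    def n_mutations(self) -> int:
        return sum(self.positions.values())


def _runs(values: np.ndarray):
    """Maximal runs of equal value: (starts, ends-exclusive, run values)."""
    n = len(values)
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.empty(change.size + 1, dtype=np.int64)
    starts[0] = 0
    starts[1:] = change
    ends = np.empty_like(starts)
    ends[:-1] = change
    ends[-1] = n
    return starts, ends, values[starts]


def _peak_runs(run_values: np.ndarray) -> np.ndarray:
    """Indices of local-maximum runs with positive value."""
    r = len(run_values)
    if r == 1:
        return (
            np.array([0], dtype=np.int64)
            if run_values[0] > 0
            else np.array([], dtype=np.int64)
        )
    is_max = np.empty(r, dtype=bool)
    is_max[0] = run_values[0] > run_values[1]
    is_max[-1] = run_values[-1] > run_values[-2]
    if r > 2:
        is_max[1:-1] = (run_values[1:-1] > run_values[:-2]) & (
            run_values[1:-1] > run_values[2:]
        )
    is_max &= run_values > 0
    return np.flatnonzero(is_max)


def find_spans(curve: np.ndarray) -> list[Span]:
    """Raw cluster spans, inclusive, partitioning [0, L).

    Empty when the curve is identically zero. Between two consecutive peaks
    there is exactly one local-minimum run (run values strictly alternate);
    it is split at its midpoint between the two clusters.
    """
    values = np.round(np.asarray(curve, dtype=float), _ROUND_DECIMALS)
    starts, ends, run_values = _runs(values)
    peaks = _peak_runs(run_values)
    if peaks.size == 0:
        return []
    length = len(values)
    lefts = [0]
    rights: list[int] = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        between = run_values[a + 1 : b]
        m = a + 1 + int(np.argmin(between))
        s, e = int(starts[m]), int(ends[m]) - 1  # inclusive minimum plateau
        cut = s + (e - s) // 2
        rights.append(cut)
        lefts.append(cut + 1)
    rights.append(length - 1)
    return [
        (l, r, int(starts[p]), float(run_values[p]))
        for l, r, p in zip(lefts, rights, peaks)
    ]


def merge_spans(spans: Sequence[Span], w_cluster: int) -> list[Span]:
    """Merge spans whose consecutive raw peaks lie within ``w_cluster``.

    Transitive closure over consecutive peaks: a chain of peaks each within
    ``w_cluster`` of the next collapses into one span. The merged peak is the
    member peak with the largest height; leftmost on ties.
    """
    if not spans:
        return []
    merged: list[Span] = []
    group: list[Span] = [spans[0]]
    for span in spans[1:]:
        if span[2] - group[-1][2] <= w_cluster:
            group.append(span)
        else:
            merged.append(_collapse(group))
            group = [span]
    merged.append(_collapse(group))
    return merged


def _collapse(group: list[Span]) -> Span:
    if len(group) == 1:
        return group[0]
    best = group[0]
    for span in group[1:]:
        if span[3] > best[3]:  # strict: leftmost wins ties
            best = span
    return (group[0][0], group[-1][1], best[2], best[3])


def detect_clusters(
    curve: np.ndarray, positions, element_id: Optional[str] = None
) -> list[Cluster]:
    """Raw clusters of a smoothing curve, each collecting its mutated positions.

    ``positions`` is the multiset of element indices the curve was computed
    from. Returns clusters sorted by peak; together their spans partition the
    element, so every mutation lands in exactly one cluster.
    """
    return _attach_positions(find_spans(curve), positions, element_id)


def merge_clusters(clusters: list[Cluster], w_cluster: int = 11) -> list[Cluster]:
    """Merge adjacent clusters whose raw peaks are within ``w_cluster`` positions.

    Input must be sorted by peak (as :func:`detect_clusters` returns).
    """
    if not clusters:
        return []
    spans = [(cl.left, cl.right, cl.peak, cl.peak_height) for cl in clusters]
    merged_spans = merge_spans(spans, w_cluster)
    positions: Counter = Counter()
    for cl in clusters:
        positions.update(cl.positions)
    return _attach_counts(merged_spans, positions, clusters[0].element_id)


def detect_and_merge(
    curve: np.ndarray,
    positions,
    w_cluster: int = 11,
    element_id: Optional[str] = None,
) -> list[Cluster]:
    """Detect raw clusters and merge them in one step."""
    spans = merge_spans(find_spans(curve), w_cluster)
    return _attach_positions(spans, positions, element_id)


def _attach_positions(spans, positions, element_id):
    counts = Counter(int(p) for p in np.asarray(positions, dtype=np.int64))
    return _attach_counts(spans, counts, element_id)


def _attach_counts(spans, counts, element_id):
    clusters = []
    for left, right, peak, height in spans:
        inside = {p: c for p, c in sorted(counts.items()) if left <= p <= right}
        clusters.append(
            Cluster(
                left=left,
                right=right,
                peak=peak,
                positions=inside,
                peak_height=height,
                element_id=element_id,
            )
        )
    return clusters


def filter_clusters(
    clusters: list[Cluster], min_cluster_mutations: int = 2
) -> list[Cluster]:
    """Drop clusters supported by fewer than ``min_cluster_mutations`` mutations."""
    return [cl for cl in clusters if cl.n_mutations >= min_cluster_mutations]
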