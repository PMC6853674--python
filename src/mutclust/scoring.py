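"""Cluster and element clustering scores.

A cluster's score combines how many of the element's mutations it captures
(the *number*) with how tightly they sit around the cluster peak (the
*shape*): each mutated position contributes the percentage of the element's
mutations it carries, geometrically discounted by its distance to the peak,

    score = sum over positions p in the cluster of
            100 * (m_p / M) / sqrt(2)^|p - peak|

where m_p is the mutation count at p and M the element's total mutation
count. A cluster holding all M mutations at its peak scores exactly 100; at
equal mutation counts, tighter clusters score higher than diffuse ones.
Element scores are the sum of their surviving clusters' scores.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clustering import Cluster

#: per-position geometric distance discount base
DISTANCE_DISCOUNT = np.sqrt(2.0)


def score_cluster(cluster: Cluster, total_mutations: int) -> float:
    """Score one cluster given the element's total mutation count ``M``."""
    if total_mutations <= 0:
        raise ValueError("element has no mutations; cluster score undefined")
    score = 0.0
    for pos, count in cluster.positions.items():
        score += 100.0 * (count / total_mutations) / DISTANCE_DISCOUNT ** abs(pos - cluster.peak)
    return score


def score_positions(
    positions: np.ndarray, counts: np.ndarray, peak: int, total_mutations: int
) -> float:
    """Vectorized cluster score from parallel position/count arrays."""
    d = np.abs(positions - peak)
    return float(100.0 / total_mutations * np.sum(counts * np.exp2(-0.5 * d)))


@dataclass(frozen=True)
class ElementScore:
    """Per-element clustering summary: sum of surviving cluster scores."""

    element_id: str
    score: float
    n_clusters: int
    n_mutations: int


def score_element(
    clusters: Sequence[Cluster],
    element_id: str = "",
    n_mutations: int = 0,
) -> ElementScore:
    """Sum already-computed cluster scores into an element score (0 if none)."""
    total = float(sum(cl.score for cl in clusters)) if clusters else 0.0
    return ElementScore(
        element_id=element_id,
        score=total,
        n_clusters=len(clusters),
        n_mutations=n_mutations,
    )
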