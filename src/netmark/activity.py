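"""Subnetwork activity inference, t-score ranking and top-K marker selection.

The activity of a subnetwork G = {g_1, ..., g_n} in a sample is the sum of
its member genes' LLR values in that sample, A(G) = sum_i lambda(x_i) —
an aggregation of the probabilistic evidence each member contributes.
Clusters are ranked by the absolute two-sample t statistic of their activity
between the phenotypes, and the top K (default 50) become the marker set.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np

from .data import Marker, MarkerSet
from .discriminative import LLRStore, t_score

logger = logging.getLogger(__name__)

__all__ = [
    "subnetwork_activity",
    "activity_matrix",
    "rank_markers",
    "select_top_k",
]

DEFAULT_TOP_K = 50


def subnetwork_activity(cluster: Iterable[str], llrs: LLRStore) -> np.ndarray:
    """Per-sample activity vector: sum of member-gene LLR profiles."""
    members = list(cluster)
    if not members:
        raise ValueError("cluster must be non-empty")
    rows = [llrs.index(g) for g in members]  # raises ValueError on unknown gene
    return llrs.lam[rows].sum(axis=0)


def activity_matrix(clusters: Mapping[str, Iterable[str]],
                    llrs: LLRStore) -> tuple[tuple[str, ...], np.ndarray]:
    """Activity vectors for every cluster, keyed and ordered by exemplar id."""
    exemplars = tuple(sorted(clusters))
    mat = np.vstack([subnetwork_activity(clusters[e], llrs) for e in exemplars])
    return exemplars, mat


def rank_markers(clusters: Mapping[str, Iterable[str]], llrs: LLRStore,
                 provenance: Mapping[str, object] | None = None) -> MarkerSet:
    """Rank clusters by descending |t| of activity; ties break on exemplar id."""
    if not clusters:
        raise ValueError("no clusters to rank")
    scored = []
    for exemplar in sorted(clusters):
        members = tuple(sorted(clusters[exemplar]))
        act = subnetwork_activity(members, llrs)
        t = t_score(act, llrs.labels, llrs.t_variant)
        scored.append(Marker(genes=members, exemplar=exemplar, t_score=t))
    scored.sort(key=lambda mk: (-abs(mk.t_score), mk.exemplar))
    return MarkerSet(markers=tuple(scored), provenance=dict(provenance or {}))


def select_top_k(markers: MarkerSet, k: int = DEFAULT_TOP_K) -> MarkerSet:
    """Keep the first min(k, available) markers of an already-ranked set."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(markers.markers):
        logger.warning("requested top %d markers but only %d available",
                       k, len(markers.markers))
    kept = markers.markers[: min(k, len(markers.markers))]
    prov = dict(markers.provenance)
    prov["top_k"] = k
    prov["n_selected"] = len(kept)
    return MarkerSet(markers=kept, provenance=prov)
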