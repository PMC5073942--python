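"""Fusion of topological and discriminative-power similarity.

Two integration modes produce the directed gene-gene similarity s(i, k) that
affinity propagation consumes, defined only on *candidate pairs* (network
neighbors, optionally distance <= 2):

* product:  s(i, k) = s_T(i, k) * s_DP(i, k)
* linear:   s(i, k) = beta * s_T(i, k) + (1 - beta) * sDP_hat(i, k),
            where sDP_hat is s_DP min-max rescaled to [0, 1] over the full
            candidate-pair set.

The affinity-propagation preference (uniform self-similarity c) is set so
that only a small lower-tail fraction (default 1 %) of directed pair
similarities falls at or below c, giving every gene a comparable chance to
become an exemplar. Non-candidate pairs have no similarity (treated as -inf
by the clustering stage), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import networkx as nx
import numpy as np

from .data import InducedDataset, PPINetwork
from .discriminative import LLRStore, build_llr_store, dp_similarity
from .topology import topo_similarity

__all__ = [
    "SimilarityGraph",
    "candidate_pairs",
    "product_similarity",
    "rescale_dp",
    "linear_combination",
    "set_preference",
    "build_similarity_graph",
]


@dataclass(frozen=True)
class SimilarityGraph:
    """Sparse directed similarity over candidate pairs plus uniform preference."""

    nodes: tuple[str, ...]
    src: np.ndarray        # edge source indices into nodes
    dst: np.ndarray        # edge destination indices into nodes
    values: np.ndarray     # s(src, dst)
    preference: float
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.src) == len(self.dst) == len(self.values)):
            raise ValueError("edge arrays must have equal length")
        if len(self.values) == 0:
            raise ValueError("similarity graph has no candidate pairs")
        if not np.isfinite(self.preference):
            raise ValueError("preference must be finite")
        directed = set(zip(self.src.tolist(), self.dst.tolist()))
        if any((k, i) not in directed for i, k in directed):
            raise ValueError("both directions of every candidate pair required")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def with_preference(self, c: float) -> "SimilarityGraph":
        return replace(self, preference=float(c))

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {
            (self.nodes[i], self.nodes[k]): float(v)
            for i, k, v in zip(self.src, self.dst, self.values)
        }


def candidate_pairs(net: PPINetwork, policy: str = "adjacent") -> list[tuple[str, str]]:
    """Directed candidate pairs: network edges, or all pairs within distance 2."""
    if policy not in ("adjacent", "within2"):
        raise ValueError(f"unknown candidate-pair policy: {policy!r}")
    pairs: list[tuple[str, str]] = []
    if policy == "adjacent":
        for u, v in net.graph.edges:
            pairs.append((u, v))
            pairs.append((v, u))
    else:
        for u in net.graph.nodes:
            reach = nx.single_source_shortest_path_length(net.graph, u, cutoff=2)
            pairs.extend((u, v) for v in reach if v != u)
    return pairs


def product_similarity(s_t: float, s_dp: float) -> float:
    """Product integration; preserves the sign of s_DP, damped by s_T."""
    return s_t * s_dp


def rescale_dp(values) -> np.ndarray:
    """Min-max rescale s_DP values to [0, 1] over the full candidate-pair set.

    A constant collection maps to 0.5 by convention.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rescale an empty collection")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.full_like(values, 0.5)
    return (values - lo) / (hi - lo)


def linear_combination(s_t: float, s_dp_hat: float, beta: float) -> float:
    """Convex combination beta * s_T + (1 - beta) * sDP_hat."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    return beta * s_t + (1.0 - beta) * s_dp_hat


def set_preference(values, quantile: float = 0.01) -> float:
    """Lower-tail percentile of directed similarities used as preference c."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot set preference from an empty collection")
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    return float(np.percentile(values, 100.0 * quantile))


def build_similarity_graph(
    induced: InducedDataset,
    mode: str = "product",
    index: str = "tversky",
    alpha: float = 0.5,
    beta: float = 0.5,
    policy: str = "adjacent",
    tversky_a: float = 1.0,
    tversky_b: float = 0.0,
    include_self: bool = True,
    t_variant: str = "welch",
    use_abs_t: bool = True,
    preference_quantile: float = 0.01,
    clamp_negative_dp: bool = False,
    llr_store: LLRStore | None = None,
) -> SimilarityGraph:
    """Compose s_DP and s_T into the directed similarity graph for clustering.

    ``clamp_negative_dp`` optionally clips negative s_DP to 0 before the
    product integration (sensitivity switch; off by default).
    """
    if mode not in ("product", "linear"):
        raise ValueError(f"unknown integration mode: {mode!r}")
    pairs = candidate_pairs(induced.network, policy)
    if not pairs:
        raise ValueError("no candidate pairs (edgeless induced network)")

    store = llr_store if llr_store is not None else build_llr_store(
        induced.expression.values, induced.expression.labels,
        induced.expression.gene_ids, t_variant)
    row = {g: i for i, g in enumerate(store.gene_ids)}

    nodes = tuple(sorted({p for pair in pairs for p in pair}))
    node_idx = {n: i for i, n in enumerate(nodes)}

    t_gene = np.abs(store.t) if use_abs_t else store.t

    # one t_ik per unordered pair, shared by both directions
    unordered = {tuple(sorted(p)) for p in pairs}
    t_pair: dict[tuple[str, str], float] = {}
    for u, v in unordered:
        t_uv = store.pair_t(row[u], row[v])
        t_pair[(u, v)] = abs(t_uv) if use_abs_t else t_uv

    src, dst, s_dp_vals, s_t_vals = [], [], [], []
    for i, k in pairs:
        ti, tk = t_gene[row[i]], t_gene[row[k]]
        tik = t_pair[tuple(sorted((i, k)))]
        s_dp_vals.append(dp_similarity(ti, tk, tik, alpha))
        s_t_vals.append(topo_similarity(induced.network, i, k, index,
                                        tversky_a, tversky_b, include_self))
        src.append(node_idx[i])
        dst.append(node_idx[k])

    s_dp_arr = np.asarray(s_dp_vals)
    s_t_arr = np.asarray(s_t_vals)
    if mode == "product":
        if clamp_negative_dp:
            s_dp_arr = np.maximum(s_dp_arr, 0.0)
        values = s_t_arr * s_dp_arr
    else:
        values = beta * s_t_arr + (1.0 - beta) * rescale_dp(s_dp_arr)

    c = set_preference(values, preference_quantile)
    meta = {
        "mode": mode, "topo_index": index, "alpha": alpha,
        "beta": beta if mode == "linear" else None,
        "tversky_a": tversky_a, "tversky_b": tversky_b,
        "include_self": include_self, "pair_policy": policy,
        "t_variant": t_variant, "use_abs_t": use_abs_t,
        "preference_quantile": preference_quantile,
        "clamp_negative_dp": clamp_negative_dp,
    }
    return SimilarityGraph(
        nodes=nodes, src=np.asarray(src, dtype=np.int64),
        dst=np.asarray(dst, dtype=np.int64), values=values,
        preference=c, meta=meta)
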