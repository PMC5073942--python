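"""Sparse affinity propagation on the directed candidate-pair similarity graph.

Standard responsibility/availability message passing, restricted to the
sparse support of the similarity graph (absent pairs behave as s = -inf):

    r(i,k) <- s(i,k) - max_{k' != k} [a(i,k') + s(i,k')]
    a(i,k) <- min{0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k))}   (i != k)
    a(k,k) <- sum_{i' != k} max(0, r(i',k))

Both messages are damped. A tiny seeded jitter breaks exact similarity ties
deterministically. Convergence is declared when the exemplar set is stable
for ``conv_window`` consecutive iterations. Exemplars collect every gene
whose best (a + r) choice points at them; genes whose choice is not a
self-declared exemplar fall back to their best exemplar neighbor by
similarity, or become singletons if they have none — so the result is always
a partition of the clusterable genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .integration import SimilarityGraph

logger = logging.getLogger(__name__)

__all__ = ["APConfig", "ClusteringResult", "cluster", "net_similarity"]


@dataclass(frozen=True)
class APConfig:
    damping: float = 0.7
    max_iter: int = 2000
    conv_window: int = 200
    noise_scale: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.damping < 1.0:
            raise ValueError("damping must lie in [0.5, 1)")
        if not self.max_iter >= self.conv_window >= 1:
            raise ValueError("require max_iter >= conv_window >= 1")


@dataclass(frozen=True)
class ClusteringResult:
    """Exemplar assignment partitioning the clusterable genes."""

    exemplar_of: Mapping[str, str]
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        for g, e in self.exemplar_of.items():
            if self.exemplar_of.get(e) != e:
                raise ValueError(f"exemplar of {g!r} is not its own exemplar")

    @property
    def clusters(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for g, e in self.exemplar_of.items():
            out.setdefault(e, set()).add(g)
        return {e: frozenset(m) for e, m in out.items()}

    @property
    def exemplars(self) -> frozenset[str]:
        return frozenset(e for e in self.exemplar_of.values())

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


def _edge_arrays(sims: SimilarityGraph, cfg: APConfig):
    """Canonical (src, dst, s) arrays with self edges appended, src-sorted."""
    n = sims.n_nodes
    src = np.concatenate([sims.src, np.arange(n)])
    dst = np.concatenate([sims.dst, np.arange(n)])
    s = np.concatenate([sims.values.astype(float),
                        np.full(n, float(sims.preference))])
    rng = np.random.default_rng(cfg.seed)
    s = s + cfg.noise_scale * rng.standard_normal(len(s))
    order = np.lexsort((dst, src))
    return src[order], dst[order], s[order]


def cluster(sims: SimilarityGraph, cfg: APConfig = APConfig()) -> ClusteringResult:
    n = sims.n_nodes
    src, dst, s = _edge_arrays(sims, cfg)
    m = len(s)
    lam = cfg.damping

    # group boundaries: src is sorted and every node has a self edge,
    # so source groups are exactly the node ids 0..n-1 in order
    src_starts = np.searchsorted(src, np.arange(n))
    src_counts = np.diff(np.append(src_starts, m))
    self_idx = np.flatnonzero(src == dst)

    perm_d = np.lexsort((src, dst))
    dst_sorted = dst[perm_d]
    dst_starts = np.searchsorted(dst_sorted, np.arange(n))

    r = np.zeros(m)
    a = np.zeros(m)
    edge_ids = np.arange(m)

    prev_ex: np.ndarray | None = None
    stable = 0
    it = 0
    for it in range(1, cfg.max_iter + 1):
        # responsibilities
        tmp = a + s
        gmax = np.maximum.reduceat(tmp, src_starts)
        rep_max = np.repeat(gmax, src_counts)
        is_max = tmp == rep_max
        first = np.minimum.reduceat(np.where(is_max, edge_ids, m), src_starts)
        tmp2 = tmp.copy()
        tmp2[first] = -np.inf
        gmax2 = np.maximum.reduceat(tmp2, src_starts)
        r_new = s - rep_max
        r_new[first] = s[first] - gmax2
        r = lam * r + (1.0 - lam) * r_new

        # availabilities
        rp = np.maximum(r, 0.0)
        rp[self_idx] = r[self_idx]
        totals = np.add.reduceat(rp[perm_d], dst_starts)  # r(k,k) + S(k)
        a_new = totals[dst] - rp
        a_clipped = np.minimum(a_new, 0.0)
        a_clipped[self_idx] = a_new[self_idx]  # a(k,k) = S(k)
        a = lam * a + (1.0 - lam) * a_clipped

        ex = (a + r)[self_idx] > 0
        if prev_ex is not None and np.array_equal(ex, prev_ex):
            stable += 1
            if stable >= cfg.conv_window:
                break
        else:
            stable = 0
        prev_ex = ex

    converged = stable >= cfg.conv_window
    if not converged:
        logger.warning("affinity propagation did not converge in %d iterations",
                       cfg.max_iter)

    # final assignment: best (a + r) over candidates(i) + {i}
    crit = a + r
    gmax = np.maximum.reduceat(crit, src_starts)
    rep_max = np.repeat(gmax, src_counts)
    first = np.minimum.reduceat(
        np.where(crit == rep_max, edge_ids, m), src_starts)
    choice = dst[first]

    is_exemplar = choice == np.arange(n)
    if not is_exemplar.any():
        best = int(np.argmax(crit[self_idx]))
        is_exemplar[best] = True
        choice[best] = best

    # reassignment of genes whose choice is not a self-declared exemplar
    exemplar_set = set(np.flatnonzero(is_exemplar).tolist())
    assign = choice.copy()
    for i in range(n):
        if is_exemplar[i]:
            assign[i] = i
            continue
        if assign[i] in exemplar_set:
            continue
        lo, hi = src_starts[i], src_starts[i] + src_counts[i]
        mask = np.array([dst[j] in exemplar_set and dst[j] != i
                         for j in range(lo, hi)])
        if mask.any():
            cand = np.arange(lo, hi)[mask]
            assign[i] = dst[cand[np.argmax(s[cand])]]
        else:
            assign[i] = i
            exemplar_set.add(i)

    # exemplar refinement (standard finalization): within each cluster,
    # re-elect the member that maximizes the incoming similarity sum,
    # provided every other member can reach it on the sparse support
    edge_val = {(int(src[e]), int(dst[e])): s[e] for e in range(m)}
    members_of: dict[int, list[int]] = {}
    for i in range(n):
        members_of.setdefault(int(assign[i]), []).append(i)
    for ex, members in members_of.items():
        if len(members) < 2:
            continue
        best_e, best_score = ex, -np.inf
        for cand in members:
            score = 0.0
            for i in members:
                if i == cand:
                    continue
                v = edge_val.get((i, cand))
                if v is None:
                    score = -np.inf
                    break
                score += v
            if score > best_score or (score == best_score and cand < best_e):
                best_e, best_score = cand, score
        if best_e != ex and np.isfinite(best_score):
            for i in members:
                assign[i] = best_e

    exemplar_of = {sims.nodes[i]: sims.nodes[int(assign[i])] for i in range(n)}
    return ClusteringResult(exemplar_of=exemplar_of, iterations=it,
                            converged=converged)


def net_similarity(sims: SimilarityGraph, result: ClusteringResult) -> float:
    """AP objective: sum of s(i, exemplar(i)) with s(k,k) = preference c.

    Returns -inf if any assignment uses a pair absent from the graph.
    """
    table = sims.as_dict()
    total = 0.0
    for g, e in result.exemplar_of.items():
        if g == e:
            total += sims.preference
        else:
            v = table.get((g, e))
            if v is None:
                return float("-inf")
            total += v
    return total
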