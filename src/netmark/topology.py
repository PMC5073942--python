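"""Neighborhood-overlap association indices on the PPI network.

The topological similarity between proteins i and k is computed from their
interaction-partner sets N_i, N_k:

* Jaccard        |Ni & Nk| / |Ni | Nk|
* Kulczynski     ((|Ni & Nk|/|Ni|) + (|Ni & Nk|/|Nk|)) / 2
* Tversky(a, b)  |Ni & Nk| / (|Ni & Nk| + a|Ni - Nk| + b|Nk - Ni|)

Tversky with (a, b) = (1, 1) is Jaccard and with (0.5, 0.5) is Dice; the
default asymmetric weights (1, 0) reduce it to |Ni & Nk| / |Ni|, rewarding a
candidate member i whose partners are contained in the exemplar k's. Dice and
Ochiai are provided for rank-comparison support only. Indices never use
common non-neighbors, and every index returns 0 whenever a denominator would
vanish. By default each protein is included in its own neighborhood, so
directly interacting proteins with no shared third partner still score > 0.
"""

from __future__ import annotations

import math

from .data import PPINetwork

__all__ = [
    "jaccard",
    "kulczynski",
    "tversky",
    "dice",
    "ochiai",
    "topo_similarity",
    "TOPO_INDICES",
]


def jaccard(ni: frozenset, nk: frozenset) -> float:
    union = len(ni | nk)
    if union == 0:
        return 0.0
    return len(ni & nk) / union


def kulczynski(ni: frozenset, nk: frozenset) -> float:
    if not ni or not nk:
        return 0.0
    inter = len(ni & nk)
    return 0.5 * (inter / len(ni) + inter / len(nk))


def tversky(ni: frozenset, nk: frozenset, a: float = 1.0, b: float = 0.0) -> float:
    if a < 0 or b < 0:
        raise ValueError("Tversky weights must be nonnegative")
    inter = len(ni & nk)
    denom = inter + a * len(ni - nk) + b * len(nk - ni)
    if denom == 0:
        return 0.0
    return inter / denom


def dice(ni: frozenset, nk: frozenset) -> float:
    total = len(ni) + len(nk)
    if total == 0:
        return 0.0
    return 2.0 * len(ni & nk) / total


def ochiai(ni: frozenset, nk: frozenset) -> float:
    if not ni or not nk:
        return 0.0
    return len(ni & nk) / math.sqrt(len(ni) * len(nk))


TOPO_INDICES = ("jaccard", "kulczynski", "tversky")


def topo_similarity(net: PPINetwork, i: str, k: str, index: str = "jaccard",
                    tversky_a: float = 1.0, tversky_b: float = 0.0,
                    include_self: bool = True) -> float:
    """Topological similarity s_T(i, k) over the chosen association index.

    Directional convention: i is the candidate member, k the potential
    exemplar, so the (asymmetric) Tversky index puts N_i first.
    """
    ni = net.neighbors(i, include_self=include_self)
    nk = net.neighbors(k, include_self=include_self)
    if index == "jaccard":
        return jaccard(ni, nk)
    if index == "kulczynski":
        return kulczynski(ni, nk)
    if index == "tversky":
        return tversky(ni, nk, tversky_a, tversky_b)
    raise ValueError(f"unknown topological index: {index!r}")
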