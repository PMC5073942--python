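"""Independent reference implementations used as oracles in tests.

These are deliberately written in a different style from the package
(bit vectors instead of sets, exhaustive enumeration instead of message
passing) so that agreement is evidence of correctness, not of shared code.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --- bit-vector association indices over an explicit universe ---------------

def to_bits(members, universe) -> np.ndarray:
    idx = {u: i for i, u in enumerate(universe)}
    v = np.zeros(len(universe), dtype=bool)
    for m in members:
        v[idx[m]] = True
    return v


def bit_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.count_nonzero(a | b)
    return np.count_nonzero(a & b) / union if union else 0.0


def bit_kulczynski(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.count_nonzero(a), np.count_nonzero(b)
    if na == 0 or nb == 0:
        return 0.0
    inter = np.count_nonzero(a & b)
    return 0.5 * (inter / na + inter / nb)


def bit_tversky(a: np.ndarray, b: np.ndarray, wa: float, wb: float) -> float:
    inter = np.count_nonzero(a & b)
    denom = inter + wa * np.count_nonzero(a & ~b) + wb * np.count_nonzero(b & ~a)
    return inter / denom if denom else 0.0


def bit_dice(a: np.ndarray, b: np.ndarray) -> float:
    total = np.count_nonzero(a) + np.count_nonzero(b)
    return 2.0 * np.count_nonzero(a & b) / total if total else 0.0


def bit_ochiai(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.count_nonzero(a), np.count_nonzero(b)
    if na == 0 or nb == 0:
        return 0.0
    return np.count_nonzero(a & b) / math.sqrt(na * nb)


# --- exhaustive exemplar-set search for the AP objective ---------------------

def best_exemplar_partition(nodes, sim: dict, preference: float):
    """Maximize sum_i s(i, exemplar(i)) (+ preference per exemplar) by brute
    force over all non-empty exemplar subsets.

    ``sim`` maps directed pairs (i, k) to similarity; absent pairs are
    forbidden assignments. Returns (best objective, one optimal assignment).
    """
    nodes = list(nodes)
    best_val = -np.inf
    best_assign = None
    for r in range(1, len(nodes) + 1):
        for exemplars in itertools.combinations(nodes, r):
            ex_set = set(exemplars)
            total = preference * len(exemplars)
            assign = {}
            feasible = True
            for i in nodes:
                if i in ex_set:
                    assign[i] = i
                    continue
                options = [(sim[(i, k)], k) for k in exemplars if (i, k) in sim]
                if not options:
                    feasible = False
                    break
                val, k = max(options)
                total += val
                assign[i] = k
            if feasible and total > best_val:
                best_val = total
                best_assign = assign
    return best_val, best_assign
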