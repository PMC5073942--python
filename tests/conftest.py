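from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from netmark.data import (ExpressionDataset, GeneProteinMap, InducedDataset,
                          PPINetwork, overlay)
from netmark.integration import SimilarityGraph

settings.register_profile(
    "ci", derandomize=True, max_examples=100,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)


@pytest.fixture
def path_graph() -> PPINetwork:
    """A - B - C."""
    return PPINetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def small_dataset(rng) -> InducedDataset:
    """Five-node induced dataset with one clearly shifted pair of genes.

    Network: A-B-C plus D-E; genes A and B carry a strong class-mean shift.
    """
    net = PPINetwork.from_edges([("A", "B"), ("B", "C"), ("D", "E")])
    genes = ("A", "B", "C", "D", "E")
    n_per = 15
    labels = np.array([1] * n_per + [2] * n_per)
    values = rng.normal(0.0, 1.0, size=(5, 2 * n_per))
    values[0, :n_per] += 2.5
    values[1, :n_per] += 2.5
    expr = ExpressionDataset(gene_ids=genes, values=values, labels=labels)
    return overlay(expr, net, GeneProteinMap.identity(genes))


def make_block_sims(rng: np.random.Generator, n: int, preference: float = -1.0,
                    lo: float = 5.0, hi: float = 6.0) -> SimilarityGraph:
    """Two well-separated similarity blocks; no cross-block candidate pairs."""
    cut = n // 2
    blocks = [range(0, cut), range(cut, n)]
    src, dst, vals = [], [], []
    for block in blocks:
        for i in block:
            for k in block:
                if i != k:
                    src.append(i)
                    dst.append(k)
                    vals.append(float(rng.uniform(lo, hi)))
    nodes = tuple(f"N{i}" for i in range(n))
    return SimilarityGraph(nodes=nodes, src=np.array(src), dst=np.array(dst),
                           values=np.array(vals), preference=preference)
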