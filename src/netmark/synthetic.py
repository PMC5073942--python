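"""Seeded generator of PPI networks with planted modules and two-class
Gaussian expression, providing ground truth for recovery benchmarks.

The network is a planted-partition graph: genes are split into disjoint
modules, within-module edges appear with probability ``p_in`` and all other
pairs with probability ``p_out`` (p_in > p_out). A subset of modules is
flagged as "disease modules": their genes get a mean shift of ``delta``
within-class standard deviations in phenotype 1, while every other gene is
pure noise in both classes. All randomness flows from a single master seed
through named substreams, so network, expression and fold randomness can be
varied independently.

Defaults mirror the package's benchmark conditions: 300 genes in 30 modules
of 10, p_in = 0.6, p_out = 0.01, 3 disease modules, delta = 1.5, 50 samples
per class, unit noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import ExpressionDataset, GeneProteinMap, MarkerSet, PPINetwork

__all__ = ["SyntheticSpec", "GroundTruth", "generate_network",
           "generate_expression", "generate_dataset", "recovery_score",
           "write_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 300
    n_modules: int = 30
    module_size_range: tuple[int, int] = (10, 10)
    within_module_edge_prob: float = 0.6
    background_edge_prob: float = 0.01
    n_disease_modules: int = 3
    effect_size: float = 1.5          # class-mean shift in units of noise sd
    n_samples_per_class: int = 50
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.module_size_range
        if not (0 <= self.background_edge_prob <= 1
                and 0 <= self.within_module_edge_prob <= 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if self.n_disease_modules > self.n_modules:
            raise ValueError("more disease modules than modules")
        if self.effect_size < 0:
            raise ValueError("effect size must be nonnegative")
        if not 1 <= lo <= hi or self.n_modules * lo > self.n_genes:
            raise ValueError("module sizes infeasible for n_genes")

_STREAMS = {"network": 0, "expression": 1, "folds": 2}


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[name]])


@dataclass(frozen=True)
class GroundTruth:
    """Planted module membership and disease flags."""

    module_of: dict[str, int]                 # gene -> module index
    disease_modules: frozenset[int]
    modules: tuple[tuple[str, ...], ...] = field(default=())

    def disease_genes(self) -> frozenset[str]:
        return frozenset(g for g, m in self.module_of.items()
                         if m in self.disease_modules)


def generate_network(spec: SyntheticSpec) -> tuple[PPINetwork, GroundTruth]:
    """Planted-partition network with flagged disease modules."""
    rng = _substream(spec.seed, "network")
    lo, hi = spec.module_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_modules)
    while sizes.sum() > spec.n_genes:
        sizes[int(np.argmax(sizes))] -= 1
    width = len(str(spec.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]

    module_of: dict[str, int] = {}
    modules: list[tuple[str, ...]] = []
    cursor = 0
    for m, size in enumerate(sizes):
        members = genes[cursor: cursor + size]
        cursor += size
        modules.append(tuple(members))
        for g in members:
            module_of[g] = m
    # leftover genes are background: module index -1
    for g in genes[cursor:]:
        module_of[g] = -1

    edges: list[tuple[str, str]] = []
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = genes[i], genes[j]
            same = module_of[gi] == module_of[gj] and module_of[gi] >= 0
            p = spec.within_module_edge_prob if same else spec.background_edge_prob
            if p > 0 and rng.random() < p:
                edges.append((gi, gj))

    disease = frozenset(
        sorted(rng.choice(spec.n_modules, size=spec.n_disease_modules,
                          replace=False).tolist()))
    net = PPINetwork.from_edges(edges, nodes=genes)
    truth = GroundTruth(module_of=module_of, disease_modules=disease,
                        modules=tuple(modules))
    return net, truth


def generate_expression(net: PPINetwork, truth: GroundTruth,
                        spec: SyntheticSpec) -> ExpressionDataset:
    """Class-conditional Gaussian expression with planted mean shifts.

    Background genes are N(0, sigma^2) in both classes; disease-module genes
    are N(delta * sigma, sigma^2) in phenotype 1 and N(0, sigma^2) in
    phenotype 2.
    """
    rng = _substream(spec.seed, "expression")
    genes = sorted(net.proteins)
    n1 = n2 = spec.n_samples_per_class
    labels = np.array([1] * n1 + [2] * n2)
    values = rng.normal(0.0, spec.noise_sigma, size=(len(genes), n1 + n2))
    disease = truth.disease_genes()
    shift = spec.effect_size * spec.noise_sigma
    for r, g in enumerate(genes):
        if g in disease:
            values[r, :n1] += shift
    sample_ids = tuple(f"S{i + 1:03d}" for i in range(n1 + n2))
    return ExpressionDataset(gene_ids=tuple(genes), values=values,
                             labels=labels, sample_ids=sample_ids)


def generate_dataset(spec: SyntheticSpec):
    """Convenience: network, ground truth, expression, identity mapping."""
    net, truth = generate_network(spec)
    expr = generate_expression(net, truth, spec)
    mapping = GeneProteinMap.identity(expr.gene_ids)
    return net, truth, expr, mapping


def recovery_score(markers: MarkerSet, truth: GroundTruth) -> float:
    """Jaccard between top-marker gene union and planted disease-gene union."""
    recovered = set(markers.gene_union())
    disease = set(truth.disease_genes())
    if not recovered and not disease:
        return 1.0
    union = recovered | disease
    if not union:
        return 0.0
    return len(recovered & disease) / len(union)


def write_dataset(outdir: str | Path, net: PPINetwork, truth: GroundTruth,
                  expr: ExpressionDataset, spec: SyntheticSpec) -> dict[str, Path]:
    """Write expression TSV, label TSV, edge list, mapping and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "network": outdir / "network.tsv",
        "mapping": outdir / "mapping.tsv",
        "truth": outdir / "truth.json",
    }
    header = "gene_id\t" + "\t".join(expr.sample_ids)
    rows = [header]
    for g, row in zip(expr.gene_ids, expr.values):
        rows.append(g + "\t" + "\t".join(f"{v:.6g}" for v in row))
    paths["expression"].write_text("\n".join(rows) + "\n")
    paths["labels"].write_text(
        "".join(f"{s}\t{l}\n" for s, l in zip(expr.sample_ids, expr.labels)))
    paths["network"].write_text(
        "".join(f"{u}\t{v}\n" for u, v in sorted(net.edges())))
    paths["mapping"].write_text("".join(f"{g}\t{g}\n" for g in expr.gene_ids))
    truth_payload = {
        "spec": {k: getattr(spec, k) for k in (
            "n_genes", "n_modules", "module_size_range",
            "within_module_edge_prob", "background_edge_prob",
            "n_disease_modules", "effect_size", "n_samples_per_class",
            "noise_sigma", "seed")},
        "module_of": truth.module_of,
        "disease_modules": sorted(truth.disease_modules),
    }
    paths["truth"].write_text(json.dumps(truth_payload, indent=2, sort_keys=True) + "\n")
    return paths
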