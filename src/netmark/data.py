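"""Domain types and I/O for expression matrices, PPI networks, mappings and markers.

The analysis operates on an *induced* dataset: the PPI subgraph restricted to
proteins whose genes are measured, with exactly one expression profile attached
to every node. :func:`overlay` produces that object from the three user inputs
(expression matrix, edge list, gene-protein mapping table).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "PPINetwork",
    "GeneProteinMap",
    "InducedDataset",
    "Marker",
    "MarkerSet",
    "read_expression",
    "read_network",
    "read_gene_protein_map",
    "overlay",
    "write_markers",
    "read_markers",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """Genes x samples expression matrix with a binary phenotype per sample.

    Labels are coded 1 (positive class, e.g. metastatic) and 2. Expression is
    used as provided; a log scale is assumed by the Gaussian class model
    downstream but not enforced here.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_samples), float64
    labels: np.ndarray  # shape (n_samples,), int, values in {1, 2}
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if values.ndim != 2 or values.shape[0] != len(self.gene_ids):
            raise ValueError("values must be a (genes x samples) matrix")
        if labels.shape != (values.shape[1],):
            raise ValueError("label vector length must equal sample count")
        if not set(np.unique(labels)) <= {1, 2}:
            raise ValueError("phenotype labels must be coded 1 or 2")
        for phen in (1, 2):
            if int(np.sum(labels == phen)) < 2:
                raise ValueError(f"phenotype {phen} has fewer than 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return replace(self, gene_ids=tuple(gene_ids), values=self.values[rows])

    def with_labels(self, labels: np.ndarray) -> "ExpressionDataset":
        return replace(self, labels=np.asarray(labels, dtype=int))


@dataclass(frozen=True)
class PPINetwork:
    """Undirected PPI graph: no self-loops, no duplicate edges."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"network contains {len(loops)} self-loop(s)")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   nodes: Iterable[str] = ()) -> "PPINetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        n_loops = 0
        for u, v in edges:
            if u == v:
                n_loops += 1
                continue
            g.add_edge(u, v)
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        return cls(g)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_proteins(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_interactions(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def neighbors(self, protein: str, include_self: bool = False) -> frozenset[str]:
        ns = set(self.graph.neighbors(protein))
        if include_self:
            ns.add(protein)
        return frozenset(ns)

    def subgraph(self, proteins: Iterable[str]) -> "PPINetwork":
        return PPINetwork(nx.Graph(self.graph.subgraph(proteins)))


@dataclass(frozen=True)
class GeneProteinMap:
    """Many-to-many (gene_id, protein_id) pairs; resolved to 1:1 by overlay."""

    pairs: tuple[tuple[str, str], ...]

    @classmethod
    def identity(cls, ids: Iterable[str]) -> "GeneProteinMap":
        return cls(tuple((i, i) for i in ids))

    def genes_for(self, protein: str) -> list[str]:
        return [g for g, p in self.pairs if p == protein]

    def proteins_for(self, gene: str) -> list[str]:
        return [p for g, p in self.pairs if g == gene]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.pairs)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p for _, p in self.pairs)


@dataclass(frozen=True)
class InducedDataset:
    """Expression overlaid onto the network: one expression row per node.

    ``expression.gene_ids`` are node (protein) identifiers after overlay;
    ``node_gene`` records which source gene each node carries.
    """

    network: PPINetwork
    expression: ExpressionDataset
    node_gene: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.expression.gene_ids) != self.network.proteins:
            raise ValueError("expression rows and network nodes must coincide")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.expression.gene_ids

    def isolated_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.network.graph.degree(n) == 0]


@dataclass(frozen=True)
class Marker:
    """One subnetwork marker: member genes led by an exemplar, scored by |t|."""

    genes: tuple[str, ...]
    exemplar: str
    t_score: float

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("marker must contain at least one gene")
        if self.exemplar not in self.genes:
            raise ValueError("exemplar must be a member gene")


@dataclass(frozen=True)
class MarkerSet:
    """Ranked, pairwise-disjoint subnetwork markers with provenance metadata."""

    markers: tuple[Marker, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.markers:
            if seen.intersection(m.genes):
                raise ValueError("marker member sets must be pairwise disjoint")
            seen.update(m.genes)
        scores = [abs(m.t_score) for m in self.markers]
        if any(a < b - 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValueError("markers must be ordered by descending |t|")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def gene_union(self) -> frozenset[str]:
        return frozenset(g for m in self.markers for g in m.genes)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_MISSING_ROW_FRACTION = 0.10  # rows with more missing than this are dropped


def read_expression(path: str | Path, labels: str | Path | Sequence[int]) -> ExpressionDataset:
    """Read a tab-delimited genes x samples matrix plus phenotype labels.

    The matrix file has gene ids in the first column and sample ids in the
    header. ``labels`` is either a two-column TSV (sample_id, phenotype in
    {1,2}) or an explicit per-sample label sequence. Duplicate gene rows are
    collapsed by their arithmetic mean; rows with a small fraction of missing
    values are mean-imputed, heavily missing rows are dropped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"no sample columns found in {path}")
    sample_ids = [str(c) for c in df.columns]

    if isinstance(labels, (str, Path)):
        lab = pd.read_csv(labels, sep="\t", header=None, comment="#",
                          names=["sample_id", "phenotype"], dtype=str)
        # tolerate a header row in the label file
        if not lab.iloc[0, 1].strip().lstrip("+-").isdigit():
            lab = lab.iloc[1:]
        lab_map = dict(zip(lab["sample_id"].astype(str),
                           lab["phenotype"].astype(int)))
        missing = [s for s in sample_ids if s not in lab_map]
        if missing:
            raise ValueError(f"missing phenotype label for sample(s): {missing}")
        label_vec = np.array([lab_map[s] for s in sample_ids], dtype=int)
    else:
        label_vec = np.asarray(list(labels), dtype=int)
        if label_vec.shape != (len(sample_ids),):
            raise ValueError("label vector length must equal sample count")

    values = df.apply(pd.to_numeric, errors="coerce")
    values.index = values.index.astype(str)

    # collapse duplicated gene rows by arithmetic mean
    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        logger.warning("collapsing %d duplicated gene row(s) by mean", n_dup)
        values = values.groupby(level=0, sort=False).mean()

    # missing-value policy: impute sparse gaps from the row mean, drop the rest
    mat = values.to_numpy(dtype=float)
    finite = np.isfinite(mat)
    frac_missing = 1.0 - finite.mean(axis=1)
    keep = frac_missing <= _MISSING_ROW_FRACTION
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d row(s) with >%.0f%% missing values",
                       n_dropped, 100 * _MISSING_ROW_FRACTION)
    mat, finite = mat[keep], finite[keep]
    gene_ids = tuple(values.index[keep])
    if np.any(~finite):
        row_means = np.nanmean(np.where(finite, mat, np.nan), axis=1)
        rows, cols = np.nonzero(~finite)
        mat[rows, cols] = row_means[rows]
        logger.info("imputed %d missing value(s) from row means", len(rows))

    return ExpressionDataset(gene_ids=gene_ids, values=mat,
                             labels=label_vec, sample_ids=tuple(sample_ids))


def read_network(path: str | Path, dialect: str = "edge_tsv") -> PPINetwork:
    """Read an undirected PPI network from a two-column edge list or SIF file.

    SIF lines are ``source<TAB>relation<TAB>target [target ...]``; every
    listed target yields one edge. Self-loops are dropped (and counted),
    duplicate edges are merged.
    """
    if dialect not in ("edge_tsv", "sif"):
        raise ValueError(f"unknown network dialect: {dialect!r}")
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if dialect == "edge_tsv":
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected two columns")
                edges.append((fields[0], fields[1]))
            else:  # sif
                if len(fields) == 1:
                    nodes.append(fields[0])  # isolated node, SIF convention
                    continue
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed SIF line")
                src = fields[0]
                edges.extend((src, tgt) for tgt in fields[2:])
    if not edges and not nodes:
        raise ValueError(f"empty network file: {path}")
    return PPINetwork.from_edges(edges, nodes=nodes)


def read_gene_protein_map(path: str | Path) -> GeneProteinMap:
    """Read a two-column TSV of (gene_id, protein_id) pairs."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValueError(f"empty mapping file: {path}")
    return GeneProteinMap(tuple(pairs))


def overlay(expr: ExpressionDataset, net: PPINetwork,
            mapping: GeneProteinMap) -> InducedDataset:
    """Overlay expression onto the network, yielding the induced dataset.

    Proteins without a measured, mapped gene are removed and vice versa.
    A protein mapped to several measured genes keeps the gene with the
    largest expression variance; a gene mapped to several proteins is
    replicated onto each node so every node carries exactly one profile.
    """
    measured = set(expr.gene_ids)
    gene_row = {g: i for i, g in enumerate(expr.gene_ids)}

    candidates: dict[str, list[str]] = {}
    for g, p in mapping.pairs:
        if g in measured and p in net.proteins:
            candidates.setdefault(p, []).append(g)
    if not candidates:
        raise ValueError("no overlap between expression genes and network proteins")

    variances = expr.values.var(axis=1, ddof=1)
    node_gene: dict[str, str] = {}
    for p, genes in candidates.items():
        # ties broken lexicographically for determinism
        node_gene[p] = max(sorted(set(genes)), key=lambda g: variances[gene_row[g]])

    kept = sorted(node_gene)
    induced_net = net.subgraph(kept)
    rows = np.array([gene_row[node_gene[p]] for p in kept])
    induced_expr = ExpressionDataset(
        gene_ids=tuple(kept), values=expr.values[rows],
        labels=expr.labels, sample_ids=expr.sample_ids)
    induced = InducedDataset(network=induced_net, expression=induced_expr,
                             node_gene=dict(node_gene))
    iso = induced.isolated_nodes()
    logger.info("induced network: %d proteins, %d interactions, %d isolated",
                induced_net.n_proteins, induced_net.n_interactions, len(iso))
    return induced


def write_markers(markers: MarkerSet, path: str | Path, format: str = "json") -> None:
    """Write markers as JSON (lossless round-trip) or GMT gene-set lines."""
    if not markers.markers:
        raise ValueError("refusing to write an empty marker set")
    path = Path(path)
    if format == "json":
        payload = {
            "provenance": dict(markers.provenance),
            "markers": [
                {"exemplar": m.exemplar, "t_score": m.t_score,
                 "genes": list(m.genes)}
                for m in markers.markers
            ],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "gmt":
        lines = []
        for rank, m in enumerate(markers.markers, start=1):
            desc = f"exemplar={m.exemplar};abs_t={abs(m.t_score):.6g}"
            lines.append("\t".join([f"subnetwork_{rank:03d}", desc, *m.genes]))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown marker format: {format!r}")


def read_markers(path: str | Path) -> MarkerSet:
    """Read a JSON marker file written by :func:`write_markers`."""
    payload = json.loads(Path(path).read_text())
    markers = tuple(
        Marker(genes=tuple(m["genes"]), exemplar=m["exemplar"],
               t_score=float(m["t_score"]))
        for m in payload["markers"]
    )
    return MarkerSet(markers=markers, provenance=payload.get("provenance", {}))
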