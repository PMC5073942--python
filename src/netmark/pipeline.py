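"""End-to-end orchestration: overlay -> similarity -> affinity propagation ->
activity ranking -> top-K markers, plus the evaluation wrapper.

Every output embeds the full run configuration and a content hash of the
inputs, so two runs with identical configuration and inputs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .activity import rank_markers, select_top_k
from .ap import APConfig, ClusteringResult, cluster
from .data import (ExpressionDataset, GeneProteinMap, InducedDataset,
                   MarkerSet, PPINetwork, overlay)
from .discriminative import build_llr_store
from .integration import SimilarityGraph, build_similarity_graph

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "DiscoverResult", "PRESETS", "run_discover",
           "run_discover_induced", "content_hash"]

# method variants named index + integration mode (jac/kul/tve x _p/_lc)
PRESETS: dict[str, dict[str, object]] = {
    "jac_p": {"topo_index": "jaccard", "mode": "product"},
    "kul_p": {"topo_index": "kulczynski", "mode": "product"},
    "tve_p": {"topo_index": "tversky", "mode": "product"},
    "jac_lc": {"topo_index": "jaccard", "mode": "linear"},
    "kul_lc": {"topo_index": "kulczynski", "mode": "linear"},
    "tve_lc": {"topo_index": "tversky", "mode": "linear"},
}


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of a discovery run.

    ``beta`` must be left unset (None) in product mode, where it is unused;
    linear mode defaults it to 0.5.
    """

    mode: str = "product"
    topo_index: str = "tversky"
    alpha: float = 0.5
    beta: float | None = None
    tversky_a: float = 1.0
    tversky_b: float = 0.0
    include_self: bool = True
    pair_policy: str = "adjacent"
    preference_quantile: float = 0.01
    t_variant: str = "welch"
    use_abs_t: bool = True
    clamp_negative_dp: bool = False
    damping: float = 0.7
    max_iter: int = 2000
    conv_window: int = 200
    top_k: int = 50
    folds: int = 5
    repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("product", "linear"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.topo_index not in ("jaccard", "kulczynski", "tversky"):
            raise ValueError(f"unknown topo_index: {self.topo_index!r}")
        if self.mode == "product" and self.beta is not None:
            raise ValueError("beta is unused in product mode; leave it unset")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta is not None and not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        APConfig(damping=self.damping, max_iter=self.max_iter,
                 conv_window=self.conv_window, seed=self.seed)  # validates
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @classmethod
    def preset(cls, name: str, **overrides) -> "RunConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset: {name!r}")
        kwargs = dict(PRESETS[name])
        if kwargs["mode"] == "linear":
            kwargs["beta"] = 0.5
        kwargs.update(overrides)
        return cls(**kwargs)

    def effective_beta(self) -> float:
        return 0.5 if self.beta is None else self.beta

    def ap_config(self) -> APConfig:
        return APConfig(damping=self.damping, max_iter=self.max_iter,
                        conv_window=self.conv_window, seed=self.seed)

    def as_dict(self) -> dict[str, object]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class DiscoverResult:
    markers: MarkerSet
    clustering: ClusteringResult
    similarity: SimilarityGraph
    induced: InducedDataset
    provenance: Mapping[str, object] = field(default_factory=dict)


def content_hash(*chunks: bytes | str) -> str:
    h = hashlib.sha256()
    for c in chunks:
        h.update(c.encode() if isinstance(c, str) else c)
    return h.hexdigest()


def _dataset_hash(induced: InducedDataset) -> str:
    expr = induced.expression
    return content_hash(
        ",".join(expr.gene_ids),
        expr.values.tobytes(),
        expr.labels.tobytes(),
        ";".join(f"{u}-{v}" for u, v in sorted(induced.network.edges())),
    )


def run_discover_induced(induced: InducedDataset, cfg: RunConfig = RunConfig()
                         ) -> DiscoverResult:
    """Discovery pipeline on an already-overlaid dataset."""
    expr = induced.expression
    store = build_llr_store(expr.values, expr.labels, expr.gene_ids,
                            cfg.t_variant)
    sims = build_similarity_graph(
        induced, mode=cfg.mode, index=cfg.topo_index, alpha=cfg.alpha,
        beta=cfg.effective_beta(), policy=cfg.pair_policy,
        tversky_a=cfg.tversky_a, tversky_b=cfg.tversky_b,
        include_self=cfg.include_self, t_variant=cfg.t_variant,
        use_abs_t=cfg.use_abs_t,
        preference_quantile=cfg.preference_quantile,
        clamp_negative_dp=cfg.clamp_negative_dp, llr_store=store)
    logger.info("similarity graph: %d nodes, %d directed pairs, preference %.4g",
                sims.n_nodes, len(sims.values), sims.preference)
    result = cluster(sims, cfg.ap_config())
    logger.info("affinity propagation: %d clusters in %d iterations (converged=%s)",
                result.n_clusters, result.iterations, result.converged)
    clusters = {e: sorted(m) for e, m in result.clusters.items()}
    provenance = {
        "config": cfg.as_dict(),
        "similarity_meta": dict(sims.meta),
        "preference": sims.preference,
        "n_clusters": result.n_clusters,
        "converged": result.converged,
        "n_isolated_nodes": len(induced.isolated_nodes()),
        "input_hash": _dataset_hash(induced),
        "netmark_version": __version__,
    }
    ranked = rank_markers(clusters, store, provenance=provenance)
    markers = select_top_k(ranked, cfg.top_k)
    return DiscoverResult(markers=markers, clustering=result,
                          similarity=sims, induced=induced,
                          provenance=provenance)


def run_discover(expr: ExpressionDataset, net: PPINetwork,
                 mapping: GeneProteinMap, cfg: RunConfig = RunConfig()
                 ) -> DiscoverResult:
    """Overlay the raw inputs, then run the discovery pipeline."""
    induced = overlay(expr, net, mapping)
    logger.info("overlay: %d/%d proteins retained, %d interactions",
                induced.network.n_proteins, net.n_proteins,
                induced.network.n_interactions)
    return run_discover_induced(induced, cfg)


def write_discover_outputs(result: DiscoverResult, outdir: str | Path) -> dict[str, Path]:
    """Persist markers (JSON + GMT) and a run summary; deterministic bytes."""
    from .data import write_markers

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers_json": outdir / "markers.json",
        "markers_gmt": outdir / "markers.gmt",
        "summary": outdir / "run_summary.json",
    }
    write_markers(result.markers, paths["markers_json"], format="json")
    write_markers(result.markers, paths["markers_gmt"], format="gmt")
    summary = {
        "provenance": {k: v for k, v in result.provenance.items()},
        "n_markers": len(result.markers),
        "marker_sizes": [len(m.genes) for m in result.markers],
        "abs_t_scores": [abs(m.t_score) for m in result.markers],
    }
    paths["summary"].write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n")
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
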