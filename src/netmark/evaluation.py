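"""Evaluation protocols: marker statistics, discriminative-power curves,
LDA/AUC cross-validation and cross-dataset reproducibility.

The reproducibility protocol follows the standard modular-marker evaluation:
markers are discovered on one dataset, their activity features are recomputed
on an independent dataset, and a linear discriminant analysis classifier is
assessed by the area under the ROC curve over stratified five-fold
cross-validation repeated for many random partitions. Gaussian LLR
parameters are always re-fit on the training folds of the dataset being
evaluated, so held-out samples never inform the class models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .data import ExpressionDataset, InducedDataset, Marker, MarkerSet
from .discriminative import build_llr_store, llr_matrix, t_score

logger = logging.getLogger(__name__)

__all__ = [
    "CVProtocol",
    "CVResult",
    "EvalReport",
    "marker_size_stats",
    "marker_overlap",
    "dp_curve",
    "cross_dataset_dp",
    "lda_auc_cv",
    "marker_cv_auc",
    "cross_dataset_eval",
]

DEFAULT_KS = (10, 20, 30, 40, 50)


@dataclass(frozen=True)
class CVProtocol:
    folds: int = 5
    repeats: int = 100
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("require folds >= 2 and repeats >= 1")

    def splitter(self, repeat: int):
        cls = StratifiedKFold if self.stratified else KFold
        return cls(n_splits=self.folds, shuffle=True,
                   random_state=(self.seed * 7919 + repeat) % (2**31 - 1))


@dataclass(frozen=True)
class CVResult:
    aucs: np.ndarray  # one pooled-out-of-fold AUC per repeat

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0


@dataclass(frozen=True)
class EvalReport:
    mean_auc: float
    auc_per_repeat: np.ndarray
    dp_curve: Mapping[int, float]
    cross_dp_curve: Mapping[int, float]
    mean_marker_size: float
    unique_gene_count: int
    n_markers: int
    overlap: float | None = None
    meta: Mapping[str, object] = field(default_factory=dict)


def marker_size_stats(markers: MarkerSet) -> tuple[float, int]:
    """Mean member count and number of unique genes across all markers."""
    if not markers.markers:
        raise ValueError("empty marker set")
    sizes = [len(m.genes) for m in markers.markers]
    return float(np.mean(sizes)), len(markers.gene_union())


def marker_overlap(markers_a: MarkerSet, markers_b: MarkerSet,
                   method: str = "jaccard") -> float:
    """Overlap of the unique member-gene unions of two marker sets.

    ``jaccard`` (default) divides by the union of the two gene sets;
    ``containment`` divides by the smaller set.
    """
    ua, ub = markers_a.gene_union(), markers_b.gene_union()
    if not ua or not ub:
        raise ValueError("both marker sets must be non-empty")
    inter = len(ua & ub)
    if method == "jaccard":
        return inter / len(ua | ub)
    if method == "containment":
        return inter / min(len(ua), len(ub))
    raise ValueError(f"unknown overlap method: {method!r}")


def _topk_means(abs_t: Sequence[float], ks: Sequence[int]) -> dict[int, float]:
    out: dict[int, float] = {}
    for k in ks:
        kk = min(k, len(abs_t))
        if kk < k:
            logger.warning("dp curve truncated: K=%d but only %d markers", k, len(abs_t))
        out[k] = float(np.mean(abs_t[:kk]))
    return out


def dp_curve(markers: MarkerSet, ks: Sequence[int] = DEFAULT_KS) -> dict[int, float]:
    """Mean |t| of the top-K markers for each K; non-increasing in K."""
    if not markers.markers:
        raise ValueError("empty marker set")
    abs_t = [abs(m.t_score) for m in markers.markers]
    return _topk_means(abs_t, ks)


def cross_dataset_dp(markers: MarkerSet, dataset_b: ExpressionDataset,
                     ks: Sequence[int] = DEFAULT_KS) -> dict[int, float]:
    """Re-evaluate marker discriminative power on an independent dataset.

    Keeps the discovery ranking order; LLR class parameters are re-fit on
    dataset B. Genes absent from B are dropped from each marker (logged);
    markers losing all genes are dropped.
    """
    store = build_llr_store(dataset_b.values, dataset_b.labels, dataset_b.gene_ids)
    present = set(dataset_b.gene_ids)
    abs_t: list[float] = []
    n_dropped_genes = 0
    n_dropped_markers = 0
    for m in markers.markers:
        kept = [g for g in m.genes if g in present]
        n_dropped_genes += len(m.genes) - len(kept)
        if not kept:
            n_dropped_markers += 1
            continue
        rows = [store.index(g) for g in kept]
        act = store.lam[rows].sum(axis=0)
        abs_t.append(abs(t_score(act, store.labels, store.t_variant)))
    if n_dropped_genes or n_dropped_markers:
        logger.info("cross-dataset transfer dropped %d gene(s), %d marker(s)",
                    n_dropped_genes, n_dropped_markers)
    if not abs_t:
        raise ValueError("no marker survives transfer to the evaluation dataset")
    return _topk_means(abs_t, ks)


def _pooled_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # phenotype 1 is the positive class
    return float(roc_auc_score((labels == 1).astype(int), scores))


def lda_auc_cv(features: np.ndarray, labels: np.ndarray,
               protocol: CVProtocol = CVProtocol()) -> CVResult:
    """Repeated stratified k-fold LDA; per-repeat AUC pools out-of-fold scores.

    ``features`` is (n_features, n_samples) — e.g. an activity matrix.
    LDA uses the lsqr solver with Ledoit-Wolf shrinkage, which stays
    well-defined when the within-class covariance is singular.
    """
    x = np.asarray(features, dtype=float).T  # samples x features
    y = np.asarray(labels, dtype=int)
    if min(np.sum(y == 1), np.sum(y == 2)) < protocol.folds:
        raise ValueError("need at least `folds` samples per class")
    aucs = np.empty(protocol.repeats)
    for rep in range(protocol.repeats):
        scores = np.empty(len(y))
        for train, test in protocol.splitter(rep).split(x, y):
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            clf.fit(x[train], y[train])
            sign = 1.0 if clf.classes_[1] == 2 else -1.0
            # orient decision scores so larger favors phenotype 1
            scores[test] = -sign * clf.decision_function(x[test])
        aucs[rep] = _pooled_auc(scores, y)
    return CVResult(aucs=aucs)


def marker_cv_auc(expr: ExpressionDataset, markers: MarkerSet,
                  protocol: CVProtocol = CVProtocol()) -> CVResult:
    """LDA/AUC cross-validation with per-fold refit of the LLR class models.

    For each training fold, Gaussian class parameters of every marker gene
    are estimated from the training samples only; activity features for all
    samples are derived from those parameters before fitting the classifier.
    """
    genes = [g for g in expr.gene_ids if g in markers.gene_union()]
    if not genes:
        raise ValueError("no marker gene measured in the evaluation dataset")
    row = {g: i for i, g in enumerate(expr.gene_ids)}
    values = expr.values[[row[g] for g in genes]]
    gidx = {g: i for i, g in enumerate(genes)}
    member_rows = [
        [gidx[g] for g in m.genes if g in gidx] for m in markers.markers
    ]
    member_rows = [r for r in member_rows if r]
    if not member_rows:
        raise ValueError("no marker survives transfer to the evaluation dataset")
    y = expr.labels
    aucs = np.empty(protocol.repeats)
    dummy = np.zeros((len(y), 1))
    for rep in range(protocol.repeats):
        scores = np.empty(len(y))
        for train, test in protocol.splitter(rep).split(dummy, y):
            lam = llr_matrix(values, y, fit_cols=train)
            feats = np.vstack([lam[r].sum(axis=0) for r in member_rows]).T
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            clf.fit(feats[train], y[train])
            sign = 1.0 if clf.classes_[1] == 2 else -1.0
            scores[test] = -sign * clf.decision_function(feats[test])
        aucs[rep] = _pooled_auc(scores, y)
    return CVResult(aucs=aucs)


def cross_dataset_eval(discovery: InducedDataset, evaluation: InducedDataset,
                       config=None,
                       protocol: CVProtocol = CVProtocol()) -> EvalReport:
    """Full protocol: discover markers on one dataset, evaluate on another.

    Runs the discovery pipeline on ``discovery``, transfers the top markers
    to ``evaluation`` (recomputing activities there) and reports the LDA/AUC
    cross-validation result together with discriminative-power curves and
    marker statistics.
    """
    from .pipeline import RunConfig, run_discover_induced  # local: avoids cycle

    cfg = config if config is not None else RunConfig()
    result = run_discover_induced(discovery, cfg)
    markers = result.markers
    cv = marker_cv_auc(evaluation.expression, markers, protocol)
    return EvalReport(
        mean_auc=cv.mean_auc,
        auc_per_repeat=cv.aucs,
        dp_curve=dp_curve(markers),
        cross_dp_curve=cross_dataset_dp(markers, evaluation.expression),
        mean_marker_size=marker_size_stats(markers)[0],
        unique_gene_count=marker_size_stats(markers)[1],
        n_markers=len(markers),
        meta=dict(markers.provenance),
    )
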