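"""Per-gene log-likelihood-ratio transform and discriminative-power similarity.

Each gene's expression is modelled with one Gaussian per phenotype; the
log-likelihood ratio (LLR)

    lambda(x) = log f1(x) - log f2(x)

converts an expression value into probabilistic evidence for phenotype 1.
The discriminative-power similarity between genes i and k is

    s_DP(i, k) = t_k + min(t_ik - t_i, t_ik - t_k) - alpha * |t_i - t_k|

where t_i is the two-sample t statistic of gene i's LLR profile between the
phenotypes and t_ik the t statistic of the summed LLR profiles. By default
the t's enter as absolute values (discriminative power is a magnitude); a
signed mode is kept for sensitivity analysis. Note s_DP is directional:
the leading t_k term belongs to the potential exemplar k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GaussianClassParams",
    "LLRStore",
    "fit_class_gaussians",
    "llr",
    "llr_profile",
    "t_score",
    "dp_similarity",
    "llr_matrix",
    "build_llr_store",
]

# Degenerate-fixture guards: class sigma is floored at RELATIVE_FLOOR times the
# pooled sigma of the gene (absolute floor ABSOLUTE_FLOOR), and |t| is capped.
RELATIVE_FLOOR = 1e-3
ABSOLUTE_FLOOR = 1e-6
T_CAP = 1e3


@dataclass(frozen=True)
class GaussianClassParams:
    """Per-phenotype Gaussian parameters for one gene."""

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValueError("class standard deviations must be positive")


def _split(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    g1, g2 = values[labels == 1], values[labels == 2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each phenotype needs at least 2 samples")
    return g1, g2


def fit_class_gaussians(values: np.ndarray, labels: np.ndarray) -> GaussianClassParams:
    """Fit per-phenotype mean and sd (ddof=1) with the variance floor applied."""
    g1, g2 = _split(values, labels)
    pooled_sd = float(np.std(values, ddof=1))
    floor = max(RELATIVE_FLOOR * pooled_sd, ABSOLUTE_FLOOR)
    return GaussianClassParams(
        mu1=float(np.mean(g1)), sigma1=max(float(np.std(g1, ddof=1)), floor),
        mu2=float(np.mean(g2)), sigma2=max(float(np.std(g2, ddof=1)), floor),
    )


def llr(x, p: GaussianClassParams):
    """Log ratio of the two class Gaussian densities at expression level x."""
    x = np.asarray(x, dtype=float)
    out = (
        np.log(p.sigma2 / p.sigma1)
        + (x - p.mu2) ** 2 / (2.0 * p.sigma2**2)
        - (x - p.mu1) ** 2 / (2.0 * p.sigma1**2)
    )
    return float(out) if out.ndim == 0 else out


def llr_profile(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample LLR vector of one gene, parameters fit on the same samples."""
    p = fit_class_gaussians(values, labels)
    return np.asarray(llr(values, p), dtype=float)


def t_score(values: np.ndarray, labels: np.ndarray, variant: str = "welch") -> float:
    """Two-sample t statistic (phenotype 1 minus phenotype 2), floored and capped.

    ``variant`` selects Welch (unequal variances, default) or pooled form.
    Degenerate zero-variance groups return 0 when the group means coincide.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    g1, g2 = _split(values, labels)
    n1, n2 = len(g1), len(g2)
    m1, m2 = float(np.mean(g1)), float(np.mean(g2))
    pooled_sd = float(np.std(np.concatenate([g1, g2]), ddof=1))
    if pooled_sd == 0.0:
        return 0.0
    floor = max(RELATIVE_FLOOR * pooled_sd, ABSOLUTE_FLOOR)
    s1 = max(float(np.std(g1, ddof=1)), floor)
    s2 = max(float(np.std(g2, ddof=1)), floor)
    if variant == "welch":
        se = np.sqrt(s1**2 / n1 + s2**2 / n2)
    else:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    return float(np.clip(t, -T_CAP, T_CAP))


def dp_similarity(t_i: float, t_k: float, t_ik: float, alpha: float = 0.5) -> float:
    """Directional discriminative-power similarity s_DP(i, k).

    Callers pass |t| scores in the default absolute mode; the formula itself
    is plain arithmetic on whatever scores it is given.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return t_k + min(t_ik - t_i, t_ik - t_k) - alpha * abs(t_i - t_k)


def llr_matrix(values: np.ndarray, labels: np.ndarray,
               fit_cols: np.ndarray | None = None) -> np.ndarray:
    """Row-wise LLR matrix; class Gaussians fit on ``fit_cols`` samples only.

    Vectorized across genes. When ``fit_cols`` is None all samples are used
    for fitting (equivalent to stacking :func:`llr_profile` row by row).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    cols = np.arange(values.shape[1]) if fit_cols is None else np.asarray(fit_cols)
    fit_vals, fit_labs = values[:, cols], labels[cols]
    g1, g2 = fit_vals[:, fit_labs == 1], fit_vals[:, fit_labs == 2]
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("each phenotype needs at least 2 fitting samples")
    pooled_sd = np.std(fit_vals, axis=1, ddof=1)
    floor = np.maximum(RELATIVE_FLOOR * pooled_sd, ABSOLUTE_FLOOR)
    mu1, mu2 = g1.mean(axis=1), g2.mean(axis=1)
    s1 = np.maximum(np.std(g1, axis=1, ddof=1), floor)
    s2 = np.maximum(np.std(g2, axis=1, ddof=1), floor)
    mu1, mu2 = mu1[:, None], mu2[:, None]
    s1, s2 = s1[:, None], s2[:, None]
    return (np.log(s2 / s1)
            + (values - mu2) ** 2 / (2.0 * s2**2)
            - (values - mu1) ** 2 / (2.0 * s1**2))


@dataclass(frozen=True)
class LLRStore:
    """LLR profiles and per-gene t scores for all nodes of an induced dataset."""

    gene_ids: tuple[str, ...]
    lam: np.ndarray           # (n_genes, n_samples) LLR matrix
    labels: np.ndarray
    t: np.ndarray             # signed per-gene t of the LLR profile
    t_variant: str = "welch"

    def index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def profile(self, gene_id: str) -> np.ndarray:
        return self.lam[self.index(gene_id)]

    def pair_t(self, i: int, k: int) -> float:
        """t score of the per-sample sum of two genes' LLR profiles."""
        return t_score(self.lam[i] + self.lam[k], self.labels, self.t_variant)


def build_llr_store(values: np.ndarray, labels: np.ndarray,
                    gene_ids: tuple[str, ...], t_variant: str = "welch") -> LLRStore:
    """Fit class Gaussians row-wise and assemble LLR profiles and t scores."""
    values = np.asarray(values, dtype=float)
    lam = np.empty_like(values)
    t = np.empty(values.shape[0])
    for r in range(values.shape[0]):
        lam[r] = llr_profile(values[r], labels)
        t[r] = t_score(lam[r], labels, t_variant)
    return LLRStore(gene_ids=tuple(gene_ids), lam=lam,
                    labels=np.asarray(labels, dtype=int), t=t,
                    t_variant=t_variant)
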