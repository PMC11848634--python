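"""Normalization and dimensionality reduction for both modalities.

RNA follows the standard single-cell recipe: drop all-zero genes upstream,
rank highly variable genes by a variance-stabilized dispersion, normalize
each cell to the median total, log1p, scale per gene, then PCA.  Hi-C maps
are band-normalized (per-cell band sums equalized to the cross-cell band
mean) and the band features PCA-reduced.  Both modalities use K_D = 100
components by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.decomposition import PCA

from contactseer.io_formats import ContactStack, ExpressionMatrix

DEFAULT_N_HVG = 2000
DEFAULT_K_D = 100


@dataclass
class Embedding:
    """An N x K_D cell embedding for one modality (or the joint space)."""

    matrix: np.ndarray
    cell_ids: list[str]
    modality: Literal["rna", "hic", "joint"]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding contains non-finite entries")
        if self.matrix.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids length must match embedding rows")

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


def select_hvg(expr: ExpressionMatrix, n_top: int = DEFAULT_N_HVG) -> np.ndarray:
    """Rank genes by clipped standardized variance against a mean-variance trend.

    The per-gene variance expected from its mean is fit by a degree-2
    polynomial in log10 space on genes with positive mean and variance;
    each gene's counts are standardized by the fitted standard deviation,
    clipped at sqrt(N), and the variance of the clipped values is the
    ranking statistic.  Ties keep gene order.  Returns the sorted (by
    original position) indices of the ``n_top`` highest-ranked genes.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    x = expr.counts
    if x.size == 0 or not x.any():
        raise ValueError("expression matrix is all zero")
    n = x.shape[0]
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    ok = (mean > 0) & (var > 0)
    score = np.zeros(x.shape[1])
    if ok.sum() >= 3:
        coef = np.polyfit(np.log10(mean[ok]), np.log10(var[ok]), deg=2)
        fitted_sd = np.sqrt(10 ** np.polyval(coef, np.log10(mean[ok])))
        clip = np.sqrt(n)
        z = (x[:, ok] - mean[ok]) / fitted_sd
        z = np.clip(z, -clip, clip)
        score[ok] = z.var(axis=0, ddof=1) if n > 1 else 0.0
    else:  # too few genes to fit a trend; fall back to raw variance
        score[ok] = var[ok]
    n_top = min(n_top, x.shape[1])
    # stable: ties broken by gene order
    order = np.argsort(-score, kind="stable")[:n_top]
    return np.sort(order)


def normalize_log_scale(expr: ExpressionMatrix,
                        return_stats: bool = False):
    """Median-total normalize per cell, log1p, then per-gene z-score.

    Zero-variance genes scale to all-zero columns; zero-total cells are left
    as zeros.  With ``return_stats`` the per-gene centering/scaling constants
    and the target total are returned so the identical transform can be
    applied to projected pseudo-expression from the other modality.
    """
    x = np.asarray(expr.counts, dtype=float)
    totals = x.sum(axis=1)
    target = float(np.median(totals[totals > 0])) if (totals > 0).any() else 1.0
    norm = np.zeros_like(x)
    nz = totals > 0
    norm[nz] = x[nz] * (target / totals[nz, None])
    logged = np.log1p(norm)
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    scaled = (logged - mu) / sd_safe
    scaled[:, sd == 0] = 0.0
    if return_stats:
        return scaled, {"target_total": target, "mean": mu, "std": sd}
    return scaled


def apply_normalization(counts: np.ndarray, stats: dict) -> np.ndarray:
    """Apply a previously fitted :func:`normalize_log_scale` transform."""
    x = np.asarray(counts, dtype=float)
    totals = x.sum(axis=1)
    norm = np.zeros_like(x)
    nz = totals > 0
    norm[nz] = x[nz] * (stats["target_total"] / totals[nz, None])
    logged = np.log1p(norm)
    sd = stats["std"]
    sd_safe = np.where(sd > 0, sd, 1.0)
    scaled = (logged - stats["mean"]) / sd_safe
    scaled[:, sd == 0] = 0.0
    return scaled


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    flip = np.sign(components[np.arange(components.shape[0]),
                              np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return flip


def pca_embed(matrix: np.ndarray, k: int = DEFAULT_K_D,
              cell_ids: list[str] | None = None,
              modality: Literal["rna", "hic", "joint"] = "rna",
              return_model: bool = False):
    """First ``k`` principal-component scores with a fixed sign convention."""
    x = np.asarray(matrix, dtype=float)
    if k > min(x.shape):
        raise ValueError(f"k={k} exceeds min(matrix shape)={min(x.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    flip = _fix_signs(pca.components_)
    scores = scores * flip
    pca.components_ = pca.components_ * flip[:, None]
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(x.shape[0])]
    emb = Embedding(scores, cell_ids, modality)
    if return_model:
        return emb, pca
    return emb


def band_features(stack: ContactStack, include_diagonal: bool = False) -> np.ndarray:
    """Band-normalized per-cell feature vectors.

    For each band (fixed ``|i - j|``), a cell's band entries are divided by
    that cell's band sum and multiplied by the band's mean sum across cells,
    so every cell's band carries equal total weight.  Empty bands stay zero.
    Features are the concatenated upper-triangle band entries.
    """
    k = stack.n_bins
    maps = stack.dense_stack()
    start = 0 if include_diagonal else 1
    feats = []
    for d in range(start, k):
        idx = (np.arange(k - d), np.arange(d, k))
        band = maps[:, idx[0], idx[1]]  # (n_cells, k-d)
        sums = band.sum(axis=1)
        mean_sum = sums.mean()
        scaled = np.zeros_like(band)
        nz = sums > 0
        scaled[nz] = band[nz] / sums[nz, None] * mean_sum
        feats.append(scaled)
    return np.concatenate(feats, axis=1)


def bandnorm_embed(stack: ContactStack, k: int = DEFAULT_K_D,
                   include_diagonal: bool = False) -> Embedding:
    """Band-normalize a contact stack and PCA-reduce cells to ``k`` dims."""
    if stack.n_cells == 0:
        raise ValueError("contact stack is empty")
    feats = band_features(stack, include_diagonal=include_diagonal)
    if not feats.any():
        raise ValueError("all contact bands are empty")
    k = min(k, stack.n_cells, feats.shape[1])
    emb = pca_embed(feats, k, cell_ids=list(stack.cell_ids), modality="hic")
    return emb
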