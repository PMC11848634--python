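"""Evaluation statistics: off-diagonal similarity, ARI, pairing accuracy.

Contact-map similarities exclude the diagonal by default because its large
values would dominate and bias the correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from contactseer.integrate import PairingTable


@dataclass
class SimilarityReport:
    pearson_offdiag: float
    cosine_offdiag: float
    n_entries: int


def _uppertri(a: np.ndarray, include_diagonal: bool) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got {a.shape}")
    iu = np.triu_indices(a.shape[0], k=0 if include_diagonal else 1)
    return a[iu]


def pearson_offdiag(a: np.ndarray, b: np.ndarray,
                    include_diagonal: bool = False) -> float:
    """Pearson correlation of the strictly-upper-triangle flattenings."""
    va, vb = _uppertri(a, include_diagonal), _uppertri(b, include_diagonal)
    if va.shape != vb.shape:
        raise ValueError("matrices must share shape")
    if va.std() == 0 or vb.std() == 0:
        warnings.warn("zero off-diagonal variance; Pearson undefined")
        return float("nan")
    return float(scipy.stats.pearsonr(va, vb).statistic)


def cosine_offdiag(a: np.ndarray, b: np.ndarray,
                   include_diagonal: bool = False) -> float:
    """Cosine similarity of the strictly-upper-triangle flattenings."""
    va, vb = _uppertri(a, include_diagonal), _uppertri(b, include_diagonal)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        warnings.warn("zero off-diagonal norm; cosine undefined")
        return float("nan")
    return float(va @ vb / (na * nb))


def similarity_report(a: np.ndarray, b: np.ndarray,
                      include_diagonal: bool = False) -> SimilarityReport:
    k = np.asarray(a).shape[0]
    n = k * (k + 1) // 2 if include_diagonal else k * (k - 1) // 2
    return SimilarityReport(
        pearson_offdiag=pearson_offdiag(a, b, include_diagonal),
        cosine_offdiag=cosine_offdiag(a, b, include_diagonal),
        n_entries=n,
    )


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index: chance-corrected clustering agreement."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label lists must have equal length")
    if len(labels_a) < 2:
        raise ValueError("need at least 2 samples")
    return float(adjusted_rand_score(labels_a, labels_b))


def matching_rate(pairs: PairingTable, true_hic_types) -> float:
    """Fraction of links whose scHi-C cell's true type matches the RNA label."""
    if len(pairs) == 0:
        raise ValueError("pairing table is empty")
    hits = sum(1 for r, h, _, lab in pairs.links if true_hic_types[h] == lab)
    return hits / len(pairs)
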