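"""Co-embedding of the two modalities, cell-cell connectivities, and pairing.

The co-embedder is pluggable: any callable with the :func:`co_embed`
signature may be registered under a name.  The built-in ``"baseline"``
projects each scHi-C cell into gene space through the association graph
(pseudo-expression = bin marginals x W^T), pushes it through the RNA
pipeline's fitted normalization and PCA, and concatenates the scores with
the RNA scores.  Pairing then assigns every scRNA cell the same-subtype
scHi-C cell of maximal connectivity; cells whose subtype has no scHi-C
representative are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from contactseer.assoc_graph import AssociationGraph
from contactseer.io_formats import ContactStack, ExpressionMatrix, GenomicFeature
from contactseer.preprocess import (
    Embedding,
    apply_normalization,
    normalize_log_scale,
    pca_embed,
)

logger = logging.getLogger(__name__)

DEFAULT_N_NEIGHBORS = 15


@dataclass
class ConnectivityMatrix:
    """Cross-modality block of the joint neighbor graph, entries in [0, 1]."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("connectivities must lie in [0, 1]")


@dataclass
class PairingTable:
    """Links from scRNA cells to same-subtype scHi-C cells."""

    links: list[tuple[int, int, float, str]]  # (rna_idx, hic_idx, connectivity, label)

    def __post_init__(self) -> None:
        rna = [l[0] for l in self.links]
        if len(set(rna)) != len(rna):
            raise ValueError("each scRNA cell may appear at most once")

    def __len__(self) -> int:
        return len(self.links)

    @property
    def rna_indices(self) -> list[int]:
        return [l[0] for l in self.links]

    @property
    def hic_indices(self) -> list[int]:
        return [l[1] for l in self.links]

    def to_tsv(self, path, rna_ids: list[str], hic_ids: list[str]) -> None:
        pd.DataFrame(
            [(rna_ids[r], hic_ids[h], c, lab) for r, h, c, lab in self.links],
            columns=["rna_cell_id", "hic_cell_id", "connectivity", "label"],
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# co-embedding

_CO_EMBEDDERS: dict[str, Callable] = {}


def register_co_embedder(name: str):
    def deco(fn: Callable) -> Callable:
        _CO_EMBEDDERS[name] = fn
        return fn
    return deco


def co_embed(
    rna_emb: Embedding,
    hic_emb: Embedding,
    graph: AssociationGraph,
    raw_rna: ExpressionMatrix,
    raw_hic_marginals: np.ndarray,
    method: str = "baseline",
) -> Embedding:
    """Joint (N_R + N_H) x K_D embedding of both modalities.

    RNA cells come first, scHi-C cells after, in input order.
    """
    if rna_emb.matrix.shape[0] == 0 or hic_emb.matrix.shape[0] == 0:
        raise ValueError("both modalities must have at least one cell")
    try:
        fn = _CO_EMBEDDERS[method]
    except KeyError:
        raise ValueError(
            f"unknown co-embedder {method!r}; registered: {sorted(_CO_EMBEDDERS)}"
        ) from None
    return fn(rna_emb, hic_emb, graph, raw_rna, raw_hic_marginals)


@register_co_embedder("baseline")
def _baseline_co_embed(
    rna_emb: Embedding,
    hic_emb: Embedding,
    graph: AssociationGraph,
    raw_rna: ExpressionMatrix,
    raw_hic_marginals: np.ndarray,
) -> Embedding:
    """Graph-projection baseline: Hi-C marginals -> gene space -> RNA PCA."""
    w = graph.weight_matrix()  # genes x bins
    if not w.any():
        raise ValueError(
            "association graph has no edges; the baseline co-embedder needs "
            "gene-bin edges to project scHi-C cells into gene space"
        )
    marg = np.asarray(raw_hic_marginals, dtype=float)
    if marg.shape[1] != w.shape[1]:
        raise ValueError(
            f"marginal bins ({marg.shape[1]}) != graph bins ({w.shape[1]})"
        )
    pseudo_expr = marg @ w.T  # (N_H, K_R)
    k = min(rna_emb.k, raw_rna.n_cells, raw_rna.n_genes)
    scaled_rna, stats = normalize_log_scale(raw_rna, return_stats=True)
    rna_scores_emb, pca = pca_embed(scaled_rna, k, cell_ids=list(raw_rna.cell_ids),
                                    modality="rna", return_model=True)
    scaled_pseudo = apply_normalization(pseudo_expr, stats)
    hic_scores = pca.transform(scaled_pseudo)
    # harmonize the modality blocks per component: center both, rescale the
    # Hi-C block to the RNA block's spread so the shared cluster structure
    # lines up while the PCA variance weighting is preserved
    rna_scores = rna_scores_emb.matrix - rna_scores_emb.matrix.mean(axis=0)
    h_mu, h_sd = hic_scores.mean(axis=0), hic_scores.std(axis=0)
    h_sd = np.where(h_sd > 0, h_sd, 1.0)
    hic_scores = (hic_scores - h_mu) / h_sd * rna_scores.std(axis=0)
    joint = np.vstack([rna_scores, hic_scores])
    return Embedding(joint, list(raw_rna.cell_ids) + list(hic_emb.cell_ids), "joint")


# ---------------------------------------------------------------------------
# connectivities and pairing


def connectivity(
    joint: Embedding,
    n_rna: int,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
) -> ConnectivityMatrix:
    """Symmetric-union kNN connectivities under cosine distance.

    Edge strength between a cell and one of its neighbors is
    ``exp(-dist / sigma_i)`` with ``sigma_i`` the mean cosine distance from
    cell i to its k nearest neighbors; the graph is symmetrized by maximum.
    The returned matrix is the N_R x N_H cross-modality block.
    """
    x = joint.matrix
    n = x.shape[0]
    if n_neighbors >= n:
        logger.warning("n_neighbors=%d >= n cells=%d; clipping", n_neighbors, n)
        n_neighbors = n - 1
    if n_neighbors < 1:
        raise ValueError("need n_neighbors >= 1")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1, metric="cosine").fit(x)
    dist, idx = nn.kneighbors(x)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    sigma = dist.mean(axis=1)
    sigma[sigma <= 0] = 1e-12
    conn = np.zeros((n, n))
    for i in range(n):
        s = np.exp(-dist[i] / sigma[i])
        conn[i, idx[i]] = np.maximum(conn[i, idx[i]], s)
    conn = np.maximum(conn, conn.T)
    conn = np.clip(conn, 0.0, 1.0)
    block = conn[:n_rna, n_rna:]
    return ConnectivityMatrix(block, joint.cell_ids[:n_rna], joint.cell_ids[n_rna:])


def transfer_labels(
    joint: Embedding,
    n_rna: int,
    rna_labels: list[str],
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
) -> list[str]:
    """Assign each scHi-C cell a subtype by kNN majority vote in joint space.

    Used when the scHi-C modality carries no subtype annotation of its own:
    each Hi-C cell takes the most common label among its ``n_neighbors``
    nearest RNA cells (cosine distance), ties broken alphabetically.
    """
    x = joint.matrix
    rna_x, hic_x = x[:n_rna], x[n_rna:]
    if len(rna_labels) != n_rna:
        raise ValueError("rna_labels must align with the RNA block")
    n_neighbors = min(n_neighbors, n_rna)
    nn = NearestNeighbors(n_neighbors=n_neighbors, metric="cosine").fit(rna_x)
    _, idx = nn.kneighbors(hic_x)
    labels_arr = np.array(rna_labels)
    out = []
    for row in idx:
        votes, counts = np.unique(labels_arr[row], return_counts=True)
        out.append(str(votes[np.argmax(counts)]))  # argmax: first alphabetically on ties
    return out


def pair_cells(
    conn: ConnectivityMatrix,
    rna_labels: list[str],
    hic_labels: list[str],
) -> PairingTable:
    """Pair every scRNA cell with its highest-connectivity same-subtype scHi-C cell.

    Different-subtype candidates are masked to -1; a cell is paired only if
    the masked maximum exceeds -1 (same-subtype candidates exist), taking the
    lowest scHi-C index on ties.  Cells labelled ``"unknown"`` are never
    paired.  Many scRNA cells may map to one scHi-C cell.
    """
    values = conn.values
    n_r, n_h = values.shape
    if len(rna_labels) != n_r or len(hic_labels) != n_h:
        raise ValueError("label lists must align with the connectivity axes")
    hic_labels_arr = np.array(hic_labels)
    links = []
    n_dropped = 0
    for i in range(n_r):
        lab = rna_labels[i]
        masked = np.where((hic_labels_arr == lab) & (lab != "unknown"),
                          values[i], -1.0)
        j = int(np.argmax(masked))  # argmax takes the first (lowest) index on ties
        if masked[j] == -1.0:
            n_dropped += 1
            continue
        links.append((i, j, float(masked[j]), lab))
    if n_dropped:
        logger.info("dropped %d scRNA cells with no same-subtype scHi-C candidate",
                    n_dropped)
    return PairingTable(links)


def pair_cells_bruteforce(
    conn: ConnectivityMatrix,
    rna_labels: list[str],
    hic_labels: list[str],
) -> PairingTable:
    """Literal loop reference for :func:`pair_cells` (test oracle)."""
    links = []
    for i in range(conn.values.shape[0]):
        best_j, best_v = -1, -1.0
        for j in range(conn.values.shape[1]):
            v = conn.values[i, j] if (
                rna_labels[i] == hic_labels[j] and rna_labels[i] != "unknown"
            ) else -1.0
            if v > best_v:
                best_j, best_v = j, v
        if best_v != -1.0:
            links.append((i, best_j, best_v, rna_labels[i]))
    return PairingTable(links)


def build_dataset(
    pairs: PairingTable,
    expr: ExpressionMatrix,
    stack: ContactStack,
    region: GenomicFeature,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Materialize (expression vector, local contact map) training pairs."""
    from contactseer.io_formats import slice_region

    if len(pairs) == 0:
        raise ValueError("pairing table is empty; cannot build a dataset")
    local = slice_region(stack, region)
    if local.n_bins < 2:
        raise ValueError(f"region yields only {local.n_bins} bin(s); need >= 2")
    dense = local.dense_stack()
    return [(expr.counts[r].copy(), dense[h].copy()) for r, h, _, _ in pairs.links]


def screen_trainable_genes(
    genes: list[GenomicFeature],
    markers: list[str],
    min_length: int = 50_000,
) -> list[str]:
    """Markers whose gene body is at least ``min_length`` bp (default 50 kb).

    At 10-kb resolution shorter genes span too few bins to train on.
    """
    lengths = {g.name: g.length for g in genes}
    return [m for m in markers if lengths.get(m, 0) >= min_length]
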