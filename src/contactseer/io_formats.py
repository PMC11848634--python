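"""Readers, writers and core containers for both modalities.

Coordinates are 0-based half-open throughout: a feature covers
``[start, end)`` and bin ``b`` at binsize ``s`` covers ``[b*s, (b+1)*s)``,
matching BED conventions.

Canonical on-disk formats are all plain text: expression as matrix-market
or dense TSV plus BED4 gene annotation and a two-column cell-label TSV;
per-cell contact maps as ``bin_i<TAB>bin_j<TAB>count`` triplet files with a
BED3 bin table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class LoadError(ValueError):
    """Raised when a file cannot be reconciled with its annotations."""


@dataclass(frozen=True)
class GenomicFeature:
    """A named interval on a chromosome (0-based, half-open)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"feature {self.name}: start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.name}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicFeature") -> bool:
        """Half-open intersection test; touching intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ExpressionMatrix:
    """Cell x gene raw-count matrix with gene coordinates and cell labels."""

    counts: np.ndarray
    genes: list[GenomicFeature]
    cell_ids: list[str]
    cell_labels: list[str]
    pseudotime: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise LoadError("counts must be a 2-D matrix")
        n, k = self.counts.shape
        if len(self.genes) != k:
            raise LoadError(
                f"gene axis mismatch: matrix has {k} columns, annotation has {len(self.genes)} genes"
            )
        if len(self.cell_ids) != n:
            raise LoadError(
                f"cell axis mismatch: matrix has {n} rows, {len(self.cell_ids)} cell ids"
            )
        if len(self.cell_labels) != n:
            raise LoadError(
                f"cell axis mismatch: matrix has {n} rows, {len(self.cell_labels)} labels"
            )
        if (self.counts < 0).any():
            raise LoadError("expression counts must be non-negative")
        if self.pseudotime is not None:
            self.pseudotime = np.asarray(self.pseudotime, dtype=float)
            if self.pseudotime.shape != (n,):
                raise LoadError("pseudotime length must equal the number of cells")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def subset_cells(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = list(idx)
        return ExpressionMatrix(
            counts=self.counts[idx],
            genes=self.genes,
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_labels=[self.cell_labels[i] for i in idx],
            pseudotime=None if self.pseudotime is None else self.pseudotime[idx],
        )


@dataclass
class ContactStack:
    """A set of per-cell symmetric contact matrices over a shared bin table."""

    binsize: int
    bins: list[GenomicFeature]
    cells: list[sp.csr_matrix] = field(repr=False)
    cell_ids: list[str] = field(default_factory=list)
    cell_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.bins)
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(len(self.cells))]
        if not self.cell_labels:
            self.cell_labels = ["unknown"] * len(self.cells)
        if len(self.cell_ids) != len(self.cells) or len(self.cell_labels) != len(self.cells):
            raise LoadError("cell id/label lists must match the number of cells")
        for i, m in enumerate(self.cells):
            if m.shape != (k, k):
                raise LoadError(f"cell {i}: matrix shape {m.shape} != bin count {k}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def dense(self, i: int) -> np.ndarray:
        return np.asarray(self.cells[i].todense(), dtype=float)

    def dense_stack(self) -> np.ndarray:
        """(n_cells, K, K) dense array of all maps."""
        return np.stack([self.dense(i) for i in range(self.n_cells)])

    def marginals(self) -> np.ndarray:
        """Cell-by-bin matrix of per-bin contact sums (row marginals)."""
        return np.stack(
            [np.asarray(m.sum(axis=1)).ravel() for m in self.cells]
        )

    def subset_cells(self, idx: Sequence[int]) -> "ContactStack":
        idx = list(idx)
        return ContactStack(
            binsize=self.binsize,
            bins=self.bins,
            cells=[self.cells[i] for i in idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_labels=[self.cell_labels[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# expression IO


def _read_bed4(path: Path) -> list[GenomicFeature]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise LoadError(f"{path}: BED4 requires chrom, start, end, name columns")
    return [
        GenomicFeature(name=str(r[3]), chrom=str(r[0]), start=int(r[1]), end=int(r[2]))
        for r in df.itertuples(index=False)
    ]


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path,
    labels_path: str | Path | None = None,
    pseudotime_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Load a cell x gene count matrix with its annotations.

    ``matrix_path`` may be matrix-market (``.mtx``, cells x genes) or a dense
    TSV whose first column is the cell id.  ``genes_path`` is BED4
    (chrom, start, end, name).  ``labels_path`` is a two-column TSV
    (cell_id, label); cells missing from it get label ``"unknown"``.
    """
    matrix_path = Path(matrix_path)
    genes = _read_bed4(Path(genes_path))
    if matrix_path.suffix == ".mtx":
        counts = np.asarray(scipy.io.mmread(matrix_path).todense(), dtype=float)
        cell_ids = [f"cell{i}" for i in range(counts.shape[0])]
    else:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        counts = df.to_numpy(dtype=float)
        cell_ids = [str(i) for i in df.index]
    if counts.shape[1] != len(genes):
        raise LoadError(
            f"gene axis mismatch: matrix has {counts.shape[1]} columns but "
            f"{genes_path} annotates {len(genes)} genes"
        )
    labels = {}
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", header=None, names=["cell_id", "label"])
        labels = dict(zip(lab["cell_id"].astype(str), lab["label"].astype(str)))
    cell_labels = [labels.get(cid, "unknown") for cid in cell_ids]
    pt = None
    if pseudotime_path is not None:
        ptdf = pd.read_csv(pseudotime_path, sep="\t", header=None, names=["cell_id", "t"])
        tmap = dict(zip(ptdf["cell_id"].astype(str), ptdf["t"].astype(float)))
        pt = np.array([tmap[cid] for cid in cell_ids])
    return ExpressionMatrix(counts, genes, cell_ids, cell_labels, pseudotime=pt)


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path,
                     genes_path: str | Path, labels_path: str | Path) -> None:
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        scipy.io.mmwrite(matrix_path, sp.coo_matrix(expr.counts))
    else:
        pd.DataFrame(expr.counts, index=expr.cell_ids,
                     columns=expr.gene_names).to_csv(matrix_path, sep="\t")
    with open(genes_path, "w") as fh:
        for g in expr.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\n")
    with open(labels_path, "w") as fh:
        for cid, lab in zip(expr.cell_ids, expr.cell_labels):
            fh.write(f"{cid}\t{lab}\n")


# ---------------------------------------------------------------------------
# contact IO


def _read_bed3(path: Path, binsize: int) -> list[GenomicFeature]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    bins = [
        GenomicFeature(name=f"bin{i}", chrom=str(r[0]), start=int(r[1]), end=int(r[2]))
        for i, r in enumerate(df.itertuples(index=False))
    ]
    for b in bins:
        if b.length != binsize:
            # last bin of a chromosome may be short; anything else is malformed
            if b.length > binsize:
                raise LoadError(
                    f"{path}: bin {b.name} has width {b.length} != binsize {binsize}"
                )
    # contiguity per chromosome
    prev: dict[str, GenomicFeature] = {}
    for b in bins:
        p = prev.get(b.chrom)
        if p is not None and b.start != p.end:
            raise LoadError(
                f"{path}: bins not contiguous on {b.chrom} at {p.end} vs {b.start}"
            )
        prev[b.chrom] = b
    return bins


def _read_triplets(path: Path, n_bins: int) -> sp.csr_matrix:
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise LoadError(f"{path}:{lineno}: expected 'bin_i bin_j count'")
            i, j = int(parts[0]), int(parts[1])
            v = float(parts[2])
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise LoadError(
                    f"{path}:{lineno}: bin index ({i},{j}) out of range for {n_bins} bins"
                )
            rows.append(i)
            cols.append(j)
            vals.append(v)
    m = sp.coo_matrix((vals, (rows, cols)), shape=(n_bins, n_bins)).tocsr()
    # mirror the stored triangle; halve the doubled diagonal
    sym = m + m.T
    sym.setdiag(sym.diagonal() / 2.0)
    sym.eliminate_zeros()
    return sym.tocsr()


def read_contacts(
    paths: Sequence[str | Path],
    binsize: int,
    bins_path: str | Path,
    cell_ids: Sequence[str] | None = None,
    labels_path: str | Path | None = None,
) -> ContactStack:
    """Load per-cell triplet files into a symmetric :class:`ContactStack`.

    Duplicate triplets (including mirrored ``(j, i)`` entries) are summed.
    """
    bins = _read_bed3(Path(bins_path), binsize)
    cells = [_read_triplets(Path(p), len(bins)) for p in paths]
    if cell_ids is None:
        cell_ids = [Path(p).stem for p in paths]
    labels = {}
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", header=None, names=["cell_id", "label"])
        labels = dict(zip(lab["cell_id"].astype(str), lab["label"].astype(str)))
    cell_labels = [labels.get(str(cid), "unknown") for cid in cell_ids]
    return ContactStack(binsize, bins, cells, list(map(str, cell_ids)), cell_labels)


def write_contacts(stack: ContactStack, out_dir: str | Path,
                   bins_path: str | Path | None = None) -> list[Path]:
    """Write each cell's upper triangle as a triplet file; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if bins_path is not None:
        with open(bins_path, "w") as fh:
            for b in stack.bins:
                fh.write(f"{b.chrom}\t{b.start}\t{b.end}\n")
    paths = []
    for cid, m in zip(stack.cell_ids, stack.cells):
        p = out_dir / f"{cid}.triplets.tsv"
        coo = sp.triu(m).tocoo()
        with open(p, "w") as fh:
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i}\t{j}\t{v:g}\n")
        paths.append(p)
    return paths


def slice_region(stack: ContactStack, region: GenomicFeature) -> ContactStack:
    """Restrict a stack to the bins fully inside ``[region.start, region.end)``."""
    idx = [
        i
        for i, b in enumerate(stack.bins)
        if b.chrom == region.chrom and b.start >= region.start and b.end <= region.end
    ]
    if not idx:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} covers no whole bin"
        )
    lo, hi = idx[0], idx[-1] + 1
    if idx != list(range(lo, hi)):
        raise ValueError("region bins are not contiguous in the bin table")
    cells = [m[lo:hi, lo:hi].tocsr() for m in stack.cells]
    return ContactStack(
        binsize=stack.binsize,
        bins=[stack.bins[i] for i in idx],
        cells=cells,
        cell_ids=list(stack.cell_ids),
        cell_labels=list(stack.cell_labels),
    )


def parse_region(text: str) -> GenomicFeature:
    """Parse ``chrom:start-end`` (0-based half-open) into a feature."""
    try:
        chrom, span = text.split(":")
        start, end = span.replace(",", "").split("-")
        return GenomicFeature(name=text, chrom=chrom, start=int(start), end=int(end))
    except ValueError as e:
        raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end") from e


def write_matrix_tsv(matrix: np.ndarray, path: str | Path, na_rep: str = "nan") -> None:
    pd.DataFrame(np.asarray(matrix)).to_csv(path, sep="\t", header=False,
                                            index=False, na_rep=na_rep)


def read_matrix_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
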