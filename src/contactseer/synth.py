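"""Coupled synthetic scRNA-seq + scHi-C generator with known ground truth.

Cells carry three latent variables: a discrete type, a pseudo-time
t ~ Uniform(0, 1), and a driver activity u ~ Uniform(0, 1).  Expression is
negative-binomial around type-specific means (each type's marker genes are
up-regulated by ``marker_effect``); contact maps are Poisson draws around a
distance-decay background plus a type-specific TAD block, a block whose
contacts grow along pseudo-time, and a set of driven interactions whose
rate increases linearly with the driver gene's latent expression.

Marker genes for a type are, by construction, the genes lying inside that
type's TAD block, so the gene-bin association graph carries the type signal
between modalities and the unpaired modalities can be matched.

``separation`` in [0, 1] scales both the marker fold-change and the TAD
contrast between 1 (types indistinguishable) and their full values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from contactseer.io_formats import ContactStack, ExpressionMatrix, GenomicFeature

BINSIZE = 10_000


@dataclass
class SynthConfig:
    n_cell_types: int = 2
    cells_per_type: int = 50
    n_genes: int = 128
    n_bins_genome: int = 100
    region_start_bin: int = 40
    n_bins_region: int = 16
    gene_length: int = 6500
    base_expression_mean: float = 5.0
    marker_effect: float = 4.0
    nb_dispersion: float = 0.15
    background_contact: float = 3.0
    tad_contrast: float = 6.0
    tad_width_bins: int = 6
    pseudotime_block: tuple[int, int] = (5, 11)  # local bins, contacts scale with t
    driver_gene: int = 20
    driver_base_mean: float = 10.0
    driven_interactions: tuple[tuple[int, int], ...] = ((1, 10), (3, 12), (6, 14))
    coupling_slope: float = 0.8
    depth_sigma: float = 0.2
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 1 or self.cells_per_type < 1:
            raise ValueError("cell counts must be positive")
        if not (0 <= self.separation <= 1):
            raise ValueError("separation must lie in [0, 1]")
        hi = self.region_start_bin + self.n_bins_region
        if hi > self.n_bins_genome:
            raise ValueError("region extends past the genome bin table")
        for i, j in self.driven_interactions:
            if not (0 <= i < self.n_bins_region and 0 <= j < self.n_bins_region):
                raise ValueError(
                    f"driven interaction ({i}, {j}) outside the {self.n_bins_region}-bin region"
                )

    # -- derived layout ----------------------------------------------------

    @property
    def region(self) -> GenomicFeature:
        return GenomicFeature(
            "region", "chr1",
            self.region_start_bin * BINSIZE,
            (self.region_start_bin + self.n_bins_region) * BINSIZE,
        )

    def type_block_local(self, k: int) -> tuple[int, int]:
        """Local bin range [lo, hi) of type k's TAD block inside the region."""
        lo = 2 + k * self.tad_width_bins
        return (min(lo, self.n_bins_region - 2),
                min(lo + self.tad_width_bins, self.n_bins_region))

    def genes(self) -> list[GenomicFeature]:
        genome_len = self.n_bins_genome * BINSIZE
        spacing = genome_len // self.n_genes
        out = []
        for i in range(self.n_genes):
            start = i * spacing
            out.append(GenomicFeature(f"g{i:04d}", "chr1", start,
                                      min(start + self.gene_length, genome_len)))
        return out

    def bins(self) -> list[GenomicFeature]:
        return [GenomicFeature(f"bin{i}", "chr1", i * BINSIZE, (i + 1) * BINSIZE)
                for i in range(self.n_bins_genome)]

    def marker_genes(self, k: int) -> list[int]:
        """Indices of type k's markers: genes inside its genomic TAD block."""
        lo, hi = self.type_block_local(k)
        block = GenomicFeature("blk", "chr1",
                               (self.region_start_bin + lo) * BINSIZE,
                               (self.region_start_bin + hi) * BINSIZE)
        return [i for i, g in enumerate(self.genes()) if g.overlaps(block)]


@dataclass
class GroundTruth:
    rna_types: list[str]
    hic_types: list[str]
    rna_t: np.ndarray
    hic_t: np.ndarray
    driver_gene: int
    driven_interactions: list[tuple[int, int]]
    marker_sets: dict[str, list[int]]
    type_blocks_local: dict[str, tuple[int, int]]
    rna_driver_u: np.ndarray = field(default_factory=lambda: np.array([]))
    hic_driver_u: np.ndarray = field(default_factory=lambda: np.array([]))


def _effective(cfg: SynthConfig, value: float) -> float:
    """Shrink a fold-change toward 1 by the separation parameter."""
    return 1.0 + cfg.separation * (value - 1.0)


def _sample_expression(cfg: SynthConfig, rng: np.random.Generator,
                       types: np.ndarray, u: np.ndarray) -> np.ndarray:
    base = rng.gamma(2.0, cfg.base_expression_mean / 2.0, size=cfg.n_genes)
    means = np.tile(base, (len(types), 1))
    eff = _effective(cfg, cfg.marker_effect)
    for k in range(cfg.n_cell_types):
        rows = np.where(types == k)[0]
        for m in cfg.marker_genes(k):
            means[rows, m] = base[m] * eff
    means[:, cfg.driver_gene] = cfg.driver_base_mean * (1.0 + 3.0 * u)
    theta = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(theta, means / theta)
    return rng.poisson(lam).astype(float)


def _expected_contact_map(cfg: SynthConfig, type_k: int, t: float,
                          driver_mean: float) -> np.ndarray:
    kh_all = cfg.n_bins_genome
    d = np.abs(np.subtract.outer(np.arange(kh_all), np.arange(kh_all)))
    lam = cfg.background_contact / (1.0 + d)
    r0 = cfg.region_start_bin
    lo, hi = cfg.type_block_local(type_k)
    contrast = _effective(cfg, cfg.tad_contrast)
    lam[r0 + lo:r0 + hi, r0 + lo:r0 + hi] *= contrast
    plo, phi = cfg.pseudotime_block
    lam[r0 + plo:r0 + phi, r0 + plo:r0 + phi] *= (0.5 + t)
    for (i, j) in cfg.driven_interactions:
        lam[r0 + i, r0 + j] += cfg.coupling_slope * driver_mean
        lam[r0 + j, r0 + i] += cfg.coupling_slope * driver_mean
    return lam


def _sample_contacts(cfg: SynthConfig, rng: np.random.Generator,
                     types: np.ndarray, t: np.ndarray,
                     u: np.ndarray) -> list[sp.csr_matrix]:
    cells = []
    n = cfg.n_bins_genome
    iu = np.triu_indices(n)
    for c in range(len(types)):
        driver_mean = cfg.driver_base_mean * (1.0 + 3.0 * u[c])
        lam = _expected_contact_map(cfg, int(types[c]), float(t[c]), driver_mean)
        depth = float(np.exp(rng.normal(0.0, cfg.depth_sigma)))
        upper = rng.poisson(lam[iu] * depth).astype(float)
        m = np.zeros((n, n))
        m[iu] = upper
        m = m + np.triu(m, k=1).T  # sample the upper triangle, mirror
        cells.append(sp.csr_matrix(m))
    return cells


def _draw_latents(cfg: SynthConfig, rng: np.random.Generator,
                  n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    types = np.repeat(np.arange(cfg.n_cell_types), cfg.cells_per_type)
    t = rng.uniform(0.0, 1.0, size=n)
    u = rng.uniform(0.0, 1.0, size=n)
    return types, t, u


def make_dataset(cfg: SynthConfig) -> tuple[ExpressionMatrix, ContactStack, GroundTruth]:
    """Paired draw: each cell yields both an expression vector and a map."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cell_types * cfg.cells_per_type
    types, t, u = _draw_latents(cfg, rng, n)
    counts = _sample_expression(cfg, rng, types, u)
    cells = _sample_contacts(cfg, rng, types, t, u)
    labels = [f"type{k}" for k in types]
    ids = [f"cell{i:04d}" for i in range(n)]
    expr = ExpressionMatrix(counts, cfg.genes(), ids, labels, pseudotime=t)
    stack = ContactStack(BINSIZE, cfg.bins(), cells, list(ids), list(labels))
    gt = GroundTruth(
        rna_types=labels, hic_types=labels, rna_t=t, hic_t=t.copy(),
        driver_gene=cfg.driver_gene,
        driven_interactions=list(cfg.driven_interactions),
        marker_sets={f"type{k}": cfg.marker_genes(k)
                     for k in range(cfg.n_cell_types)},
        type_blocks_local={f"type{k}": cfg.type_block_local(k)
                           for k in range(cfg.n_cell_types)},
        rna_driver_u=u, hic_driver_u=u.copy(),
    )
    return expr, stack, gt


def make_unpaired(cfg: SynthConfig) -> tuple[ExpressionMatrix, ContactStack, GroundTruth]:
    """Independent cell draws per modality from the same type-conditional laws."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cell_types * cfg.cells_per_type
    r_types, r_t, r_u = _draw_latents(cfg, rng, n)
    counts = _sample_expression(cfg, rng, r_types, r_u)
    h_types, h_t, h_u = _draw_latents(cfg, rng, n)
    cells = _sample_contacts(cfg, rng, h_types, h_t, h_u)
    r_labels = [f"type{k}" for k in r_types]
    h_labels = [f"type{k}" for k in h_types]
    expr = ExpressionMatrix(counts, cfg.genes(),
                            [f"rna{i:04d}" for i in range(n)], r_labels,
                            pseudotime=r_t)
    stack = ContactStack(BINSIZE, cfg.bins(), cells,
                         [f"hic{i:04d}" for i in range(n)], h_labels)
    gt = GroundTruth(
        rna_types=r_labels, hic_types=h_labels, rna_t=r_t, hic_t=h_t,
        driver_gene=cfg.driver_gene,
        driven_interactions=list(cfg.driven_interactions),
        marker_sets={f"type{k}": cfg.marker_genes(k)
                     for k in range(cfg.n_cell_types)},
        type_blocks_local={f"type{k}": cfg.type_block_local(k)
                           for k in range(cfg.n_cell_types)},
        rna_driver_u=r_u, hic_driver_u=h_u,
    )
    return expr, stack, gt
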