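"""Chromatin-dynamics statistics over pseudo-time-ordered contact maps.

Given predicted (or observed) local maps ordered by pseudo-time, this
module computes:

* migration maps — contact positions sampled proportionally to contact
  value, jittered within one bin, averaged into a super-resolution grid of
  per-cell mean pseudo-times, optionally cubic-interpolated;
* the vibration score map X_v (mean absolute change of each interaction
  between pseudo-time-adjacent maps) and the switch score map X_s (fraction
  of steps whose absolute change exceeds that interaction's vibration
  score), with the dynamic index ranking interactions by X_v;
* chromatin volume — a 3D structure from a pluggable reconstructor
  (baseline: contact-to-distance power law + classical metric MDS) whose
  convex-hull volume is tracked across pseudo-time windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.interpolate
import scipy.linalg
from scipy.spatial import ConvexHull, QhullError

from contactseer.io_formats import ContactStack


@dataclass
class PseudoTimeOrder:
    """Ascending stable-sort permutation of cells by pseudo-time."""

    t: np.ndarray
    delta: np.ndarray  # 0-based permutation; t[delta] is non-decreasing

    @property
    def sorted_t(self) -> np.ndarray:
        return self.t[self.delta]


def order_by_pseudotime(t: Sequence[float]) -> PseudoTimeOrder:
    t = np.asarray(t, dtype=float)
    if np.isnan(t).any():
        raise ValueError("pseudo-time contains NaN")
    delta = np.argsort(t, kind="stable")
    return PseudoTimeOrder(t=t, delta=delta)


# ---------------------------------------------------------------------------
# migration maps


def sample_interactions(
    contact_map: np.ndarray,
    n_draws: int,
    jitter_bins: float = 1.0,
    rng_seed: int = 0,
) -> np.ndarray:
    """Sample (i, j) positions proportional to contact value, with jitter.

    Each drawn integer position is perturbed by uniform noise in
    [-jitter_bins/2, +jitter_bins/2] per axis; at 10-kb bins jitter_bins=1
    randomizes within a 10-kb range.  Returns an (n_draws, 2) float array.
    """
    m = np.asarray(contact_map, dtype=float)
    if (m < 0).any():
        raise ValueError("contact map must be non-negative")
    total = m.sum()
    if total <= 0:
        raise ValueError("cannot sample from an all-zero contact map")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(rng_seed)
    flat = m.ravel() / total
    idx = rng.choice(m.size, size=n_draws, p=flat)
    ii, jj = np.unravel_index(idx, m.shape)
    pts = np.stack([ii, jj], axis=1).astype(float)
    pts += rng.uniform(-jitter_bins / 2, jitter_bins / 2, size=pts.shape)
    return pts


@dataclass
class MigrationMap:
    factor: int
    M: np.ndarray  # (factor*K_h, factor*K_h); NaN where no point fell


def migration_map(
    points: np.ndarray,
    times: np.ndarray,
    K_h: int,
    factor: int = 2,
    upsample: int | None = 10,
) -> tuple[MigrationMap, MigrationMap | None]:
    """Average point pseudo-times on a factor-refined grid.

    Cell (a, b) holds the mean pseudo-time of the points with
    i in [a/factor, (a+1)/factor) and j in [b/factor, (b+1)/factor);
    empty cells are NaN.  When ``upsample`` is given, the populated cells
    are cubic-interpolated onto the finer upsample grid (NaN outside the
    convex hull of populated cells).
    """
    points = np.asarray(points, dtype=float)
    times = np.asarray(times, dtype=float)
    if points.size == 0:
        raise ValueError("no points to build a migration map from")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    size = factor * K_h
    sums = np.zeros((size, size))
    counts = np.zeros((size, size))
    a = np.clip(np.floor(points[:, 0] * factor).astype(int), 0, size - 1)
    b = np.clip(np.floor(points[:, 1] * factor).astype(int), 0, size - 1)
    np.add.at(sums, (a, b), times)
    np.add.at(counts, (a, b), 1.0)
    with np.errstate(invalid="ignore"):
        M = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    raw = MigrationMap(factor=factor, M=M)
    if upsample is None:
        return raw, None
    # centers of populated coarse cells, in bin units
    aa, bb = np.nonzero(counts)
    src = np.stack([(aa + 0.5) / factor, (bb + 0.5) / factor], axis=1)
    vals = M[aa, bb]
    size_u = upsample * K_h
    grid = (np.arange(size_u) + 0.5) / upsample
    gx, gy = np.meshgrid(grid, grid, indexing="ij")
    if len(vals) >= 4:
        try:
            interp = scipy.interpolate.griddata(src, vals, (gx, gy), method="cubic")
        except QhullError:
            interp = scipy.interpolate.griddata(src, vals, (gx, gy), method="nearest")
    else:
        interp = scipy.interpolate.griddata(src, vals, (gx, gy), method="nearest")
    return raw, MigrationMap(factor=upsample, M=interp)


# ---------------------------------------------------------------------------
# vibration / switch scores


def vibration_map(ordered_maps: np.ndarray) -> np.ndarray:
    """Elementwise mean absolute difference between adjacent ordered maps."""
    maps = np.asarray(ordered_maps, dtype=float)
    if maps.ndim != 3 or maps.shape[0] < 2:
        raise ValueError("need a stack of at least 2 equally shaped maps")
    deltas = np.diff(maps, axis=0)
    return np.abs(deltas).mean(axis=0)


def switch_map(ordered_maps: np.ndarray, X_v: np.ndarray | None = None) -> np.ndarray:
    """Fraction of steps whose |change| strictly exceeds the vibration score."""
    maps = np.asarray(ordered_maps, dtype=float)
    if X_v is None:
        X_v = vibration_map(maps)
    X_v = np.asarray(X_v, dtype=float)
    if X_v.shape != maps.shape[1:]:
        raise ValueError("X_v shape does not match the maps")
    deltas = np.abs(np.diff(maps, axis=0))
    return (deltas > X_v).mean(axis=0)


def dynamic_index(
    X_v: np.ndarray, top_fraction: float = 0.05
) -> tuple[list[tuple[int, int, float]], np.ndarray]:
    """Interactions (i < j) ranked by descending vibration score.

    Ties are broken lexicographically by (i, j).  Returns the ranked list
    and a boolean K_h x K_h mask marking the top ceil(fraction * count)
    interactions (symmetric positions both set).
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must lie in (0, 1]")
    X_v = np.asarray(X_v, dtype=float)
    k = X_v.shape[0]
    iu, ju = np.triu_indices(k, k=1)
    entries = sorted(
        zip(iu.tolist(), ju.tolist(), X_v[iu, ju].tolist()),
        key=lambda e: (-e[2], e[0], e[1]),
    )
    n_top = int(np.ceil(top_fraction * len(entries)))
    mask = np.zeros_like(X_v, dtype=bool)
    for i, j, _ in entries[:n_top]:
        mask[i, j] = mask[j, i] = True
    return entries, mask


def pseudo_bulk(stack: ContactStack | np.ndarray) -> np.ndarray:
    """Elementwise mean over cells (a pseudo-bulk contact map)."""
    maps = stack.dense_stack() if isinstance(stack, ContactStack) else np.asarray(stack, dtype=float)
    if maps.ndim != 3 or maps.shape[0] == 0:
        raise ValueError("need a non-empty stack of maps")
    return maps.mean(axis=0)


# ---------------------------------------------------------------------------
# 3D reconstruction and volume

Reconstructor = Callable[[np.ndarray, float, int], np.ndarray]

_RECONSTRUCTORS: dict[str, Reconstructor] = {}


def register_reconstructor(name: str):
    def deco(fn: Reconstructor) -> Reconstructor:
        _RECONSTRUCTORS[name] = fn
        return fn
    return deco


@register_reconstructor("mds")
def _mds_reconstruct(contact_map: np.ndarray, alpha: float = 0.5,
                     rng_seed: int = 0) -> np.ndarray:
    """Metric MDS (stress majorization) on distances d_ij = (c_ij + 1)^(-alpha).

    Stress-minimizing SMACOF embeds all pairwise distances, unlike the
    truncated eigendecomposition of classical scaling which discards
    everything beyond three components; deterministic for a fixed seed.
    """
    from sklearn.manifold import smacof as _smacof

    c = np.asarray(contact_map, dtype=float)
    if (c < 0).any():
        raise ValueError("contact map must be non-negative")
    d = (c + 1.0) ** (-alpha)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    coords, _ = _smacof(d, n_components=3, random_state=rng_seed, n_init=4,
                        max_iter=1000, eps=1e-9, normalized_stress=False)
    return coords


def reconstruct_3d(contact_map: np.ndarray, alpha: float = 0.5,
                   rng_seed: int = 0, method: str = "mds") -> np.ndarray:
    """K_h x 3 coordinates for a contact map via a pluggable reconstructor."""
    c = np.asarray(contact_map, dtype=float)
    if c.shape[0] < 4:
        raise ValueError("need at least 4 bins for a 3D structure")
    try:
        fn = _RECONSTRUCTORS[method]
    except KeyError:
        raise ValueError(
            f"unknown reconstructor {method!r}; registered: {sorted(_RECONSTRUCTORS)}"
        ) from None
    return fn(c, alpha, rng_seed)


def hull_volume(coords: np.ndarray) -> float:
    """Volume of the 3D convex hull; 0 (with warning) for degenerate inputs."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 4:
        raise ValueError("need at least 4 points for a 3D hull")
    try:
        return float(ConvexHull(coords).volume)
    except QhullError:
        warnings.warn("degenerate (coplanar) point set; volume is 0")
        return 0.0


@dataclass
class VolumeSeries:
    volumes: np.ndarray
    delta_volumes: np.ndarray


def volume_series(ordered_maps: np.ndarray, windows: int = 10,
                  alpha: float = 0.5, rng_seed: int = 0,
                  method: str = "mds") -> VolumeSeries:
    """Hull volume of the pseudo-bulk map in consecutive pseudo-time windows."""
    maps = np.asarray(ordered_maps, dtype=float)
    n = maps.shape[0]
    if windows < 1:
        raise ValueError("windows must be >= 1")
    if n < windows:
        raise ValueError(f"only {n} maps for {windows} windows")
    bounds = np.linspace(0, n, windows + 1).astype(int)
    vols = []
    for w in range(windows):
        chunk = maps[bounds[w]:bounds[w + 1]]
        coords = reconstruct_3d(pseudo_bulk(chunk), alpha=alpha,
                                rng_seed=rng_seed, method=method)
        vols.append(hull_volume(coords))
    vols = np.array(vols)
    return VolumeSeries(volumes=vols, delta_volumes=np.diff(vols))
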