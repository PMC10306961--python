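"""Geometric texture features: volume, surface, and per-level fractal dimensions.

For each gray level g of a discretized image the superlevel set
``{v : level(v) >= g}`` is analysed as a binary voxel set:

* ``fractal_bc_d_<g>`` — box-counting (Minkowski) dimension: the OLS slope of
  log N(s) against log(1/s) over dyadic box sizes s = 1, 2, 4, ... anchored
  at the volume corner;
* ``fractal_c_d_<g>`` — Grassberger–Procaccia correlation dimension of the
  occupied-voxel centers (physical mm), with a seeded subsample cap to keep
  the O(M^2) pair count tractable.

Degenerate masks (empty, or with too few usable scales/points) yield NaN
(missing), never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from ..discretize import DiscretizedImage

__all__ = [
    "LevelMask",
    "FractalFit",
    "level_mask",
    "box_counting_dimension",
    "correlation_dimension",
    "volume_surface_features",
    "geometric_feature_block",
]

# seeded subsample for the O(M^2) correlation integral; fixed for determinism
_CORRDIM_SEED = 20230115
_CORRDIM_MAX_POINTS = 2000
_N_RADII = 32

GEOM_EXTRA_IDS = ("Volume_mm3", "Surface_mm2", "Surface_to_volume")


@dataclass
class LevelMask:
    """Binary occupancy field derived from one gray level of an image."""

    occupied: np.ndarray  # 3D bool
    level: int
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.occupied.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.occupied))


@dataclass
class FractalFit:
    """A log–log scaling fit with its diagnostics."""

    box_sizes: np.ndarray
    counts: np.ndarray
    dimension: float
    r2: float


def level_mask(disc: DiscretizedImage, g: int) -> LevelMask:
    """Superlevel set at gray level g: occupied where level >= g (nested in g)."""
    if not 1 <= g <= disc.L:
        raise ValueError(f"gray level {g} outside [1, {disc.L}]")
    return LevelMask(occupied=disc.levels >= g, level=int(g), spacing=disc.spacing)


def _dyadic_sizes(shape: tuple[int, ...]) -> list[int]:
    max_edge = max(shape)
    sizes = []
    s = 1
    while s <= max_edge // 2:
        sizes.append(s)
        s *= 2
    return sizes


def _block_reduce_max(a: np.ndarray, s: int) -> np.ndarray:
    """Max over s^3 blocks (grid anchored at index 0, short edge blocks padded)."""
    pad = [(0, (-n) % s) for n in a.shape]
    if any(p[1] for p in pad):
        a = np.pad(a, pad, mode="constant", constant_values=0)
    nx, ny, nz = (n // s for n in a.shape)
    return (
        a.reshape(nx, s, ny, s, nz, s).max(axis=(1, 3, 5))
    )


def _fit_loglog(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and R^2 of y against x (both already log-transformed)."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def box_counting_dimension(mask: LevelMask) -> FractalFit | None:
    """Box-counting dimension of an occupancy mask.

    Returns None (missing) for an empty mask or when fewer than 3 dyadic box
    sizes are available (image too small).
    """
    if mask.n_occupied == 0:
        return None
    sizes = _dyadic_sizes(mask.occupied.shape)
    if len(sizes) < 3:
        return None
    occ = mask.occupied.astype(np.uint8)
    counts = np.array(
        [int(np.count_nonzero(_block_reduce_max(occ, s))) for s in sizes],
        dtype=np.float64,
    )
    sizes_arr = np.array(sizes, dtype=np.float64)
    slope, r2 = _fit_loglog(np.log(1.0 / sizes_arr), np.log(counts))
    return FractalFit(box_sizes=sizes_arr, counts=counts, dimension=slope, r2=r2)


def correlation_dimension(
    mask: LevelMask,
    max_points: int = _CORRDIM_MAX_POINTS,
    n_radii: int = _N_RADII,
) -> FractalFit | None:
    """Grassberger–Procaccia correlation dimension of the occupied voxels.

    The correlation integral C(r) = 2/(M(M-1)) * #{pairs closer than r} is
    evaluated on a geometric grid of radii between the smallest and largest
    pairwise distance; the dimension is the OLS slope of log C against log r
    over the scaling window (radii between the 10th and 60th percentiles of
    the grid, where C has not yet saturated). Masks with fewer than 2
    occupied voxels, or with all points coincident, return None.
    """
    m = mask.n_occupied
    if m < 2:
        return None
    coords = np.argwhere(mask.occupied).astype(np.float64)
    coords *= np.asarray(mask.spacing)
    if coords.shape[0] > max_points:
        rng = np.random.default_rng(_CORRDIM_SEED)
        idx = rng.choice(coords.shape[0], size=max_points, replace=False)
        coords = coords[idx]
    d = pdist(coords)
    d_min = d[d > 0].min() if np.any(d > 0) else 0.0
    d_max = float(d.max())
    if d_min == 0.0 or d_max <= d_min:
        return None
    radii = np.geomspace(d_min * 1.0001, d_max, n_radii)
    n_pairs = d.size
    counts = np.searchsorted(np.sort(d), radii, side="left")  # pairs with dist < r
    c = counts / n_pairs
    # scaling window: interior radii, before C(r) saturates toward 1
    lo = int(np.floor(n_radii * 0.10))
    hi = int(np.ceil(n_radii * 0.60))
    sel = np.arange(lo, hi)
    sel = sel[c[sel] > 0]
    if sel.size < 3:
        return None
    slope, r2 = _fit_loglog(np.log(radii[sel]), np.log(c[sel]))
    return FractalFit(box_sizes=radii[sel], counts=counts[sel].astype(np.float64),
                      dimension=slope, r2=r2)


def volume_surface_features(mask: LevelMask) -> dict[str, float]:
    """Volume (mm^3), face-counted surface (mm^2) and their ratio (1/mm).

    The surface counts voxel faces between an occupied voxel and an
    unoccupied (or out-of-volume) neighbor, each weighted by its physical
    face area. An empty mask yields all-NaN.
    """
    occ = mask.occupied
    n = int(np.count_nonzero(occ))
    sx, sy, sz = mask.spacing
    if n == 0:
        return {k: float("nan") for k in GEOM_EXTRA_IDS}
    vol = n * sx * sy * sz
    face_areas = (sy * sz, sx * sz, sx * sy)
    surface = 0.0
    for ax, area in enumerate(face_areas):
        a = np.swapaxes(occ, 0, ax)
        interior = a[:-1] != a[1:]
        n_faces = int(np.count_nonzero(interior))
        n_faces += int(np.count_nonzero(a[0])) + int(np.count_nonzero(a[-1]))
        surface += n_faces * area
    return {
        "Volume_mm3": float(vol),
        "Surface_mm2": float(surface),
        "Surface_to_volume": float(surface / vol),
    }


def _box_counts_all_levels(disc: DiscretizedImage) -> tuple[list[int], np.ndarray]:
    """Occupied-box counts N_g(s) for every superlevel set g at once.

    Returns (sizes, counts) with counts shaped (L, n_sizes): the block
    maximum of the level image determines, for each box, the highest g whose
    superlevel set occupies it.
    """
    sizes = _dyadic_sizes(disc.shape)
    L = disc.L
    counts = np.zeros((L, len(sizes)), dtype=np.float64)
    for si, s in enumerate(sizes):
        bm = _block_reduce_max(disc.levels, s).ravel()
        hist = np.bincount(bm, minlength=L + 1)[1:]  # boxes whose max level == g
        counts[:, si] = hist[::-1].cumsum()[::-1]  # boxes with max level >= g
    return sizes, counts


def geometric_feature_block(
    disc: DiscretizedImage,
    reference_level: int | None = None,
    corrdim_max_points: int = _CORRDIM_MAX_POINTS,
) -> dict[str, float]:
    """Per-level fractal dimensions plus a volume/surface block.

    Emits ``fractal_bc_d_<g>__<scheme>_<L>`` and ``fractal_c_d_<g>__<scheme>_<L>``
    for every gray level g in 1..L (NaN where the superlevel set is empty or
    degenerate), and volume/surface features of the superlevel set at
    ``reference_level`` (default L//2).
    """
    L = disc.L
    scheme_tag = f"__{disc.scheme}_{L}"
    out: dict[str, float] = {}

    sizes, counts_all = _box_counts_all_levels(disc)
    log_inv_s = np.log(1.0 / np.array(sizes, dtype=np.float64))
    for g in range(1, L + 1):
        counts = counts_all[g - 1]
        if counts[0] == 0 or len(sizes) < 3:
            dim = float("nan")
        else:
            dim, _ = _fit_loglog(log_inv_s, np.log(counts))
        out[f"fractal_bc_d_{g}{scheme_tag}"] = dim

    for g in range(1, L + 1):
        fit = correlation_dimension(level_mask(disc, g), max_points=corrdim_max_points)
        out[f"fractal_c_d_{g}{scheme_tag}"] = fit.dimension if fit else float("nan")

    ref = reference_level if reference_level is not None else max(1, L // 2)
    vs = volume_surface_features(level_mask(disc, ref))
    for k, v in vs.items():
        out[f"{k}{scheme_tag}"] = v
    return out
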