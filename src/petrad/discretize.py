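"""Gray-level discretization of SUV volumes.

Two schemes are provided, mirroring the "es"/"ep" naming used throughout the
feature identifiers:

* ``es`` (equally sized): L bins of equal width spanning [min, max];
* ``ep`` (equally probable): empirical-quantile bins so each level holds an
  (as near as possible) equal number of voxels; a run of tied values is never
  split across levels.

Both schemes are order-preserving and invariant to positive affine rescaling
of the input intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import VoxelGrid

__all__ = ["DiscretizedImage", "discretize_es", "discretize_ep", "discretize"]

SCHEMES = ("es", "ep")


@dataclass
class DiscretizedImage:
    """Integer gray-level volume with values in 1..L.

    ``bin_edges`` holds L+1 non-decreasing thresholds in SUV units; for the
    ep scheme ties in the data may force merged (equal) edges.
    """

    levels: np.ndarray  # 3D int array, values in 1..L
    L: int
    scheme: str
    bin_edges: np.ndarray
    spacing: tuple[float, float, float]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        if self.levels.ndim != 3:
            raise ValueError("levels must be 3D")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.levels.size:
            lo, hi = int(self.levels.min()), int(self.levels.max())
            if lo < 1 or hi > self.L:
                raise ValueError(f"levels outside [1, {self.L}]: range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.levels.shape  # type: ignore[return-value]


def _check_L(L: int) -> int:
    L = int(L)
    if L < 2:
        raise ValueError(f"level count L must be >= 2, got {L}")
    return L


def discretize_es(grid: VoxelGrid, L: int = 128) -> DiscretizedImage:
    """Equal-size binning into L levels over [min, max].

    Bin k covers ``[min + (k-1)w, min + kw)`` with ``w = (max - min)/L``; the
    last bin is closed at the maximum. A constant image maps every voxel to
    level 1.
    """
    L = _check_L(L)
    x = grid.values
    mn = float(x.min())
    mx = float(x.max())
    if mx == mn:
        levels = np.ones(x.shape, dtype=np.int32)
        edges = np.full(L + 1, mn)
    else:
        w = (mx - mn) / L
        idx = np.floor((x - mn) / w).astype(np.int64)
        np.clip(idx, 0, L - 1, out=idx)
        levels = (idx + 1).astype(np.int32)
        edges = mn + w * np.arange(L + 1)
        edges[-1] = mx
    return DiscretizedImage(
        levels=levels, L=L, scheme="es", bin_edges=edges,
        spacing=grid.spacing, source_id=grid.case_id,
    )


def discretize_ep(grid: VoxelGrid, L: int = 128) -> DiscretizedImage:
    """Equal-probability (quantile) binning into L levels.

    With N voxels of which all values are distinct, every occupied level
    holds either floor(N/L) or ceil(N/L) voxels. A repeated value is assigned
    entirely to a single level, so level populations may be unequal when the
    data are heavily tied.
    """
    L = _check_L(L)
    x = grid.values
    flat = x.ravel()
    n = flat.size
    uniq, counts = np.unique(flat, return_counts=True)
    # voxels strictly below each unique value
    below = np.concatenate(([0], np.cumsum(counts)[:-1]))
    level_of_uniq = 1 + (below * L) // n  # fair-division rule: ties stay together
    level_of_uniq = level_of_uniq.astype(np.int32)
    pos = np.searchsorted(uniq, flat)
    levels = level_of_uniq[pos].reshape(x.shape)

    edges = np.empty(L + 1)
    edges[0] = uniq[0]
    edges[L] = uniq[-1]
    # edge k separates level k from k+1: the smallest value mapped above k
    for k in range(1, L):
        above = np.searchsorted(level_of_uniq, k, side="right")
        edges[k] = uniq[above] if above < uniq.size else uniq[-1]
    return DiscretizedImage(
        levels=levels, L=L, scheme="ep", bin_edges=edges,
        spacing=grid.spacing, source_id=grid.case_id,
    )


def discretize(grid: VoxelGrid, scheme: str, L: int = 128) -> DiscretizedImage:
    """Dispatch to :func:`discretize_es` or :func:`discretize_ep`."""
    if scheme == "es":
        return discretize_es(grid, L)
    if scheme == "ep":
        return discretize_ep(grid, L)
    raise ValueError(f"unknown scheme {scheme!r}")
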