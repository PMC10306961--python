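"""Tumor-to-normal uptake ratio (TNR) quantification.

SUVt is the mean value in the hottest ~1.0 cm^3 sub-volume, found by an
exhaustive cubic sliding-window search; SUVn is the mean over a caller-given
reference region; TNR = SUVt / SUVn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import VoxelGrid, extract_box, voxel_volume

__all__ = [
    "Region",
    "TnrResult",
    "hottest_region_mean",
    "reference_region_mean",
    "compute_tnr",
    "compute_case_tnr",
]


@dataclass(frozen=True)
class Region:
    """A rectangular sub-volume descriptor: half-open [corner, corner+shape)."""

    corner: tuple[int, int, int]
    shape: tuple[int, int, int]


@dataclass
class TnrResult:
    suv_t: float
    suv_n: float
    tnr: float
    t_region: Region | None = None
    n_region: Region | None = None


def _window_edge(grid: VoxelGrid, target_volume_cm3: float) -> int:
    """Cubic window edge (voxels) whose volume best approximates the target."""
    vv = voxel_volume(grid)
    edge = int(round((target_volume_cm3 * 1000.0 / vv) ** (1.0 / 3.0)))
    return max(1, edge)


def hottest_region_mean(
    grid: VoxelGrid, target_volume_cm3: float = 1.0
) -> tuple[float, Region]:
    """Exhaustive search for the cubic window with the maximal mean value.

    The window edge is ``round((target_volume / voxel_volume)^(1/3))`` voxels.
    Window sums are computed exactly with a 3D summed-area table, so the
    search is exhaustive over all placements.
    """
    edge = _window_edge(grid, target_volume_cm3)
    if any(n < edge for n in grid.shape):
        raise ValueError(
            f"grid shape {grid.shape} smaller than the {edge}^3 search window"
        )
    x = grid.values
    # 3D summed-area table with a zero border
    sat = np.zeros(tuple(n + 1 for n in x.shape))
    sat[1:, 1:, 1:] = x.cumsum(0).cumsum(1).cumsum(2)
    e = edge
    sums = (
        sat[e:, e:, e:] - sat[:-e, e:, e:] - sat[e:, :-e, e:] - sat[e:, e:, :-e]
        + sat[:-e, :-e, e:] + sat[:-e, e:, :-e] + sat[e:, :-e, :-e]
        - sat[:-e, :-e, :-e]
    )
    means = sums / e**3
    corner = np.unravel_index(int(np.argmax(means)), means.shape)
    region = Region(corner=tuple(int(c) for c in corner), shape=(e, e, e))
    return float(means[corner]), region


def reference_region_mean(grid: VoxelGrid, region: Region) -> float:
    """Arithmetic mean over a reference region; must be positive for TNR."""
    sub = extract_box(grid, region.corner, region.shape)
    mean = float(sub.values.mean())
    if mean <= 0:
        raise ValueError(f"reference region mean {mean} <= 0: TNR undefined")
    return mean


def compute_tnr(suv_t: float, suv_n: float) -> float:
    """TNR = SUVt / SUVn; requires SUVn > 0."""
    if suv_n <= 0:
        raise ValueError(f"SUVn must be positive, got {suv_n}")
    return suv_t / suv_n


def compute_case_tnr(
    grid: VoxelGrid, reference_region: Region, target_volume_cm3: float = 1.0
) -> TnrResult:
    """Full per-case TNR computation: hottest window mean over reference mean."""
    suv_t, t_region = hottest_region_mean(grid, target_volume_cm3)
    suv_n = reference_region_mean(grid, reference_region)
    return TnrResult(
        suv_t=suv_t,
        suv_n=suv_n,
        tnr=compute_tnr(suv_t, suv_n),
        t_region=t_region,
        n_region=reference_region,
    )
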