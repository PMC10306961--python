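"""Voxel-grid data model and NIfTI I/O.

The unit of data every stage of the pipeline consumes is a :class:`VoxelGrid`:
a 3D scalar field of SUV values together with its physical voxel spacing.
Volumes are exchanged on disk as NIfTI-1 files (gzipped accepted); headers
with flipped or permuted axes are normalized to a canonical RAS-like ordering
at load, since all downstream texture statistics are direction-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "read_nifti",
    "write_nifti",
    "extract_box",
    "voxel_volume",
]


@dataclass
class VoxelGrid:
    """A 3D scalar volume with physical voxel spacing.

    Parameters
    ----------
    values
        3D array of voxel values (SUV, dimensionless). Must be finite.
    spacing
        Per-axis voxel size in mm, all strictly positive.
    origin
        Physical coordinate (mm) of voxel ``(0, 0, 0)``.
    case_id
        Opaque case label carried through feature tables.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    case_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        n_bad = int(np.count_nonzero(~np.isfinite(self.values)))
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


def voxel_volume(grid: VoxelGrid) -> float:
    """Physical volume of one voxel in mm^3 (product of spacings)."""
    return float(np.prod(grid.spacing))


def read_nifti(path: str | Path, case_id: str | None = None) -> VoxelGrid:
    """Load a single 3D scalar NIfTI volume as a :class:`VoxelGrid`.

    The image is reoriented to the closest canonical (RAS) axis ordering;
    only spacing and origin are retained from the affine. Trailing singleton
    dimensions are squeezed; true 4D volumes are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    # tolerate a trailing singleton dimension only
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: not a 3D scalar volume (shape {data.shape})")
    if np.iscomplexobj(data):
        raise ValueError(f"{path}: not a 3D scalar volume (complex dtype)")
    data = np.asarray(data, dtype=np.float64)
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad:
        raise ValueError(f"{path}: volume contains {n_bad} non-finite voxel(s)")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VoxelGrid(
        values=data,
        spacing=tuple(float(z) for z in zooms),
        origin=origin,
        case_id=case_id if case_id is not None else path.name.split(".")[0],
    )


def write_nifti(grid: VoxelGrid, path: str | Path) -> None:
    """Write a :class:`VoxelGrid` to a NIfTI-1 file (float64, lossless)."""
    path = Path(path)
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(grid.values.astype(np.float64), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def extract_box(
    grid: VoxelGrid,
    corner: tuple[int, int, int],
    shape: tuple[int, int, int],
) -> VoxelGrid:
    """Extract a rectangular sub-volume.

    Boxes are half-open ``[corner, corner + shape)`` in 0-based voxel indices
    and must lie entirely inside the grid — out-of-bounds boxes raise rather
    than silently clipping.
    """
    corner = tuple(int(c) for c in corner)
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise ValueError(f"box shape components must be >= 1, got {shape}")
    if any(c < 0 for c in corner):
        raise ValueError(f"box corner must be non-negative, got {corner}")
    for ax in range(3):
        if corner[ax] + shape[ax] > grid.shape[ax]:
            raise ValueError(
                f"box [{corner}, {tuple(c + s for c, s in zip(corner, shape))})"
                f" exceeds grid shape {grid.shape} on axis {ax}"
            )
    sl = tuple(slice(c, c + s) for c, s in zip(corner, shape))
    new_origin = tuple(
        o + c * sp for o, c, sp in zip(grid.origin, corner, grid.spacing)
    )
    return VoxelGrid(
        values=grid.values[sl].copy(),
        spacing=grid.spacing,
        origin=new_origin,
        case_id=grid.case_id,
    )
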