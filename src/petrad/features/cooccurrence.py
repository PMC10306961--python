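"""3D gray-level co-occurrence (GLCM) and run-length (GLRLM) statistics.

Matrices are built for the 13 unique 3D lattice directions at Chebyshev
distance 1, symmetrized (GLCM), and mean-aggregated — matching the
``_b<L>_d1_mean`` suffix of the feature-id grammar. Each co-occurrence
statistic is also emitted in a "non-diagonal" (``_nd``) variant, computed on
the matrix with its diagonal removed and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..discretize import DiscretizedImage

__all__ = [
    "DIRECTIONS_3D",
    "GLCM",
    "GLRLM",
    "build_glcms",
    "aggregate_mean",
    "glcm_statistics",
    "build_glrlm",
    "glrlm_statistics",
    "cooccurrence_feature_block",
    "GLCM_STAT_IDS",
    "GLRLM_STAT_IDS",
]

# The 13 unique (up to sign) 3D lattice directions at Chebyshev distance 1.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1),
)

GLCM_STAT_NAMES = (
    "Contrast_s",
    "Homogeneity_s",
    "Homogeneity2_e",
    "Cluster_p_s",
    "Cluster_s_s",
    "Cluster_d_s",
    "Inv_Gauss_2p_s",
    "Inv_Gauss_2f_s",
)
GLCM_STAT_IDS = tuple(
    name + nd for name in GLCM_STAT_NAMES for nd in ("", "_nd")
)
GLRLM_STAT_IDS = ("GLN", "RLN", "SRE", "LRE")


@dataclass
class GLCM:
    """Symmetrized, normalized co-occurrence matrix (sums to 1)."""

    matrix: np.ndarray  # L x L, entries >= 0, total 1
    distance: int
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GLCM matrix must be square")

    @property
    def L(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GLRLM:
    """Run-length matrix: counts of maximal runs by gray level and length."""

    matrix: np.ndarray  # L x Rmax integer counts, row g-1 = level g
    direction: tuple[int, int, int]

    @property
    def n_runs(self) -> int:
        return int(self.matrix.sum())


def _pair_slices(shape, offset):
    """Slices (a, b) so that a[v] and b[v] are voxel pairs separated by offset."""
    sa, sb = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            sa.append(slice(0, n - d))
            sb.append(slice(d, n))
        else:
            sa.append(slice(-d, n))
            sb.append(slice(0, n + d))
    return tuple(sa), tuple(sb)


def build_glcms(disc: DiscretizedImage, distance: int = 1) -> list[GLCM]:
    """One symmetrized, normalized GLCM per 3D direction at the given distance.

    Directions whose offset does not fit in the image (no co-occurring pairs)
    are skipped; if no direction yields any pair the image is too small and a
    ValueError is raised.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    lv = disc.levels.astype(np.int64) - 1  # 0-based for bincount
    L = disc.L
    out: list[GLCM] = []
    for direction in DIRECTIONS_3D:
        offset = tuple(distance * d for d in direction)
        sa, sb = _pair_slices(lv.shape, offset)
        a = lv[sa].ravel()
        b = lv[sb].ravel()
        if a.size == 0:
            continue
        counts = np.bincount(a * L + b, minlength=L * L).reshape(L, L).astype(np.float64)
        counts = counts + counts.T  # symmetrize
        out.append(GLCM(matrix=counts / counts.sum(), distance=distance))
    if not out:
        raise ValueError(
            f"image of shape {disc.shape} has no voxel pairs at distance {distance}"
        )
    return out


def aggregate_mean(glcms: list[GLCM]) -> GLCM:
    """Entrywise arithmetic mean of normalized GLCMs (still sums to 1)."""
    if not glcms:
        raise ValueError("empty GLCM list")
    L = glcms[0].L
    if any(m.L != L for m in glcms):
        raise ValueError("GLCMs have differing level counts")
    mean = np.mean([m.matrix for m in glcms], axis=0)
    return GLCM(matrix=mean, distance=glcms[0].distance,
                symmetric=all(m.symmetric for m in glcms))


def _glcm_stats_core(p: np.ndarray, L: int) -> dict[str, float]:
    i = np.arange(1, p.shape[0] + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    diff = ii - jj
    clus = ii + jj - mu_i - mu_j
    istar, jstar = np.unravel_index(int(np.argmax(p)), p.shape)
    focus = ((ii - (istar + 1)) ** 2 + (jj - (jstar + 1)) ** 2) / L**2
    return {
        "Contrast_s": float(np.sum(p * diff**2)),
        "Homogeneity_s": float(np.sum(p / (1.0 + np.abs(diff)))),
        "Homogeneity2_e": float(np.sum(p / (1.0 + diff**2))),
        "Cluster_p_s": float(np.sum(p * clus**4)),
        "Cluster_s_s": float(np.sum(p * clus**3)),
        "Cluster_d_s": float(np.sum(p * np.abs(diff))),
        "Inv_Gauss_2p_s": float(np.sum(p * np.exp(-((diff / L) ** 2)))),
        "Inv_Gauss_2f_s": float(np.sum(p * np.exp(-focus))),
    }


def glcm_statistics(glcm: GLCM) -> dict[str, float]:
    """Texture statistics of a normalized GLCM.

    Emits each statistic plus its ``_nd`` variant computed on the matrix with
    diagonal cells removed and renormalized; when all mass sits on the
    diagonal the ``_nd`` variants are NaN (missing).
    """
    p = glcm.matrix
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"GLCM not normalized (sum={total})")
    out = dict(_glcm_stats_core(p, glcm.L))
    p_nd = p.copy()
    np.fill_diagonal(p_nd, 0.0)
    off_mass = p_nd.sum()
    if off_mass > 0:
        nd = _glcm_stats_core(p_nd / off_mass, glcm.L)
    else:
        nd = {k: float("nan") for k in GLCM_STAT_NAMES}
    for k in GLCM_STAT_NAMES:
        out[k + "_nd"] = nd[k]
    return out


def _step_index(coords: np.ndarray, direction: tuple[int, int, int]) -> np.ndarray:
    """Integer step count of each voxel along the direction (any nonzero axis)."""
    for ax, d in enumerate(direction):
        if d != 0:
            return coords[:, ax] * d  # d is +-1, so this is +-x
    raise ValueError("zero direction")


def build_glrlm(disc: DiscretizedImage, direction: tuple[int, int, int]) -> GLRLM:
    """Run-length matrix of maximal same-level runs along one direction.

    Every lattice line parallel to ``direction`` is scanned; each voxel
    belongs to exactly one maximal run, so total run length equals the voxel
    count.
    """
    if all(d == 0 for d in direction):
        raise ValueError("zero direction")
    lv = disc.levels
    shape = lv.shape
    # run starts: predecessor out of bounds or different level
    sa, sb = _pair_slices(shape, direction)
    same = np.zeros(shape, dtype=bool)
    same[sb] = lv[sa] == lv[sb]  # voxel equals its predecessor along direction
    starts = ~same
    ends = np.ones(shape, dtype=bool)
    ends[sa] = lv[sa] != lv[sb]  # voxel differs from its successor

    s_coords = np.argwhere(starts)
    e_coords = np.argwhere(ends)
    s_m = _step_index(s_coords, direction)
    e_m = _step_index(e_coords, direction)
    # line anchor: walk each voxel back to step 0 of its line
    d_arr = np.array(direction)
    s_anchor = s_coords - s_m[:, None] * d_arr
    e_anchor = e_coords - e_m[:, None] * d_arr

    def _order(anchor, m):
        key = (anchor[:, 0], anchor[:, 1], anchor[:, 2], m)
        return np.lexsort(key[::-1])

    so = _order(s_anchor, s_m)
    eo = _order(e_anchor, e_m)
    lengths = e_m[eo] - s_m[so] + 1
    levels_of_runs = lv[tuple(s_coords[so].T)]

    rmax = int(lengths.max())
    L = disc.L
    mat = np.zeros((L, rmax), dtype=np.int64)
    np.add.at(mat, (levels_of_runs - 1, lengths - 1), 1)
    return GLRLM(matrix=mat, direction=tuple(direction))


def glrlm_statistics(glrlm: GLRLM) -> dict[str, float]:
    """GLN, RLN and short/long-run emphasis of a run-length matrix."""
    mat = glrlm.matrix
    r = mat.sum()
    if r == 0:
        raise ValueError("empty run-length matrix")
    lengths = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    by_level = mat.sum(axis=1).astype(np.float64)
    by_length = mat.sum(axis=0).astype(np.float64)
    return {
        "GLN": float(np.sum(by_level**2) / r),
        "RLN": float(np.sum(by_length**2) / r),
        "SRE": float(np.sum(by_length / lengths**2) / r),
        "LRE": float(np.sum(by_length * lengths**2) / r),
    }


def cooccurrence_feature_block(
    disc: DiscretizedImage, distance: int = 1
) -> dict[str, float]:
    """Full GLCM + GLRLM feature block with mean aggregation over directions.

    GLCM statistics are computed on the direction-mean matrix; GLRLM
    statistics are computed per direction and averaged. Ids follow the
    ``<Stat>__<scheme>_b<L>_d<distance>_mean`` grammar.
    """
    suffix = f"__{disc.scheme}_b{disc.L}_d{distance}_mean"
    out: dict[str, float] = {}
    try:
        mean_glcm = aggregate_mean(build_glcms(disc, distance))
        for k, v in glcm_statistics(mean_glcm).items():
            out[k + suffix] = v
    except ValueError:
        for k in GLCM_STAT_IDS:
            out[k + suffix] = float("nan")

    stat_sums: dict[str, list[float]] = {k: [] for k in GLRLM_STAT_IDS}
    for direction in DIRECTIONS_3D:
        stats = glrlm_statistics(build_glrlm(disc, direction))
        for k in GLRLM_STAT_IDS:
            stat_sums[k].append(stats[k])
    for k in GLRLM_STAT_IDS:
        out[k + suffix] = float(np.mean(stat_sums[k]))
    return out
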