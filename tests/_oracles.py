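"""Independent brute-force oracles used by the tests.

Deliberately naive (python loops, sort-based statistics) and kept separate
from the package implementation they are checked against.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_oracle(levels: np.ndarray, offset: tuple[int, int, int], L: int) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix by exhaustive pair listing."""
    m = np.zeros((L, L), dtype=np.float64)
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                x2, y2, z2 = x + offset[0], y + offset[1], z + offset[2]
                if 0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz:
                    m[levels[x, y, z] - 1, levels[x2, y2, z2] - 1] += 1
    m = m + m.T
    total = m.sum()
    return m / total if total else m


def glrlm_oracle(
    levels: np.ndarray, direction: tuple[int, int, int]
) -> dict[tuple[int, int], int]:
    """Maximal-run counts {(gray level, run length): count} by direct walking."""
    nx, ny, nz = levels.shape
    runs: dict[tuple[int, int], int] = {}
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                px, py, pz = x - direction[0], y - direction[1], z - direction[2]
                if (0 <= px < nx and 0 <= py < ny and 0 <= pz < nz
                        and levels[px, py, pz] == levels[x, y, z]):
                    continue  # not the start of a maximal run
                length = 1
                cx, cy, cz = x + direction[0], y + direction[1], z + direction[2]
                while (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz
                       and levels[cx, cy, cz] == levels[x, y, z]):
                    length += 1
                    cx, cy, cz = cx + direction[0], cy + direction[1], cz + direction[2]
                key = (int(levels[x, y, z]), length)
                runs[key] = runs.get(key, 0) + 1
    return runs


def glcm_stats_oracle(p: np.ndarray, L: int) -> dict[str, float]:
    """Co-occurrence statistics by direct double loop over matrix cells."""
    n = p.shape[0]
    mu_i = sum((i + 1) * p[i, j] for i in range(n) for j in range(n))
    mu_j = sum((j + 1) * p[i, j] for i in range(n) for j in range(n))
    pmax_i, pmax_j = 0, 0
    for i in range(n):
        for j in range(n):
            if p[i, j] > p[pmax_i, pmax_j]:
                pmax_i, pmax_j = i, j
    out = {k: 0.0 for k in (
        "Contrast_s", "Homogeneity_s", "Homogeneity2_e", "Cluster_p_s",
        "Cluster_s_s", "Cluster_d_s", "Inv_Gauss_2p_s", "Inv_Gauss_2f_s")}
    for i in range(n):
        for j in range(n):
            gi, gj, w = i + 1, j + 1, p[i, j]
            d = gi - gj
            c = gi + gj - mu_i - mu_j
            out["Contrast_s"] += w * d * d
            out["Homogeneity_s"] += w / (1 + abs(d))
            out["Homogeneity2_e"] += w / (1 + d * d)
            out["Cluster_p_s"] += w * c**4
            out["Cluster_s_s"] += w * c**3
            out["Cluster_d_s"] += w * abs(d)
            out["Inv_Gauss_2p_s"] += w * math.exp(-((d / L) ** 2))
            out["Inv_Gauss_2f_s"] += w * math.exp(-((i - pmax_i) ** 2 + (j - pmax_j) ** 2) / L**2)
    return out


def first_order_oracle(x: np.ndarray) -> dict[str, float]:
    """Sort-based first-order statistics (population moment conventions)."""
    v = np.sort(np.asarray(x, dtype=np.float64).ravel())
    n = v.size
    mean = v.sum() / n
    med = (v[(n - 1) // 2] + v[n // 2]) / 2.0
    var = float(np.sum((v - mean) ** 2) / n)
    sd = math.sqrt(var)
    out = {
        "Mean__orig": float(mean),
        "Median__orig": float(med),
        "SD__orig": sd,
        "Min__orig": float(v[0]),
        "Max__orig": float(v[-1]),
        "Range__orig": float(v[-1] - v[0]),
        "Energy__orig": float(np.sum(v * v)),
        "Max_AD_md__orig": float(max(abs(v[0] - med), abs(v[-1] - med))),
    }
    if sd > 0:
        out["Skewness__orig"] = float(np.sum((v - mean) ** 3) / n / sd**3)
        out["Kurtosis__orig"] = float(np.sum((v - mean) ** 4) / n / sd**4 - 3.0)
    return out


def box_count_oracle(occ: np.ndarray, s: int) -> int:
    """Count s^3 boxes (anchored at the origin) containing >= 1 occupied voxel."""
    nx, ny, nz = occ.shape
    count = 0
    for bx in range(0, nx, s):
        for by in range(0, ny, s):
            for bz in range(0, nz, s):
                if occ[bx:bx + s, by:by + s, bz:bz + s].any():
                    count += 1
    return count
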