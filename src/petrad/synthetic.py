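"""Synthetic PET phantoms and cohorts with known ground truth.

Phantoms make no claim of scanner physics realism — they only plant the
statistical structure the downstream analysis assumes: a noisy positive
background, an ellipsoidal "tumor" carrying a correlated texture field, a
constant hottest sub-block (so the sliding-window SUVt search has an exact
target), and a disjoint reference region with a planted mean. Cohorts tie
the per-case texture parameters to log10(TNR) through a planted linear
model, so feature extraction followed by the stability protocol has a known
signal to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_model import VoxelGrid, write_nifti
from .tnr import Region, TnrResult

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "make_regression_cohort",
]


@dataclass
class PhantomSpec:
    """Generative parameters of one phantom volume."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_mean: float = 1.0
    background_sd: float = 0.05
    tumor_center_mm: tuple[float, float, float] | None = None  # default: volume center
    tumor_semi_axes_mm: tuple[float, float, float] = (18.0, 15.0, 12.0)
    tumor_base_suv: float = 4.0
    texture_corr_mm: float = 6.0
    texture_amplitude: float = 0.3
    hotspot_suv: float = 6.52
    reference_region: Region = field(
        default_factory=lambda: Region(corner=(2, 2, 2), shape=(5, 5, 5))
    )
    reference_mean: float = 2.0
    reference_sd: float = 0.0
    seed: int = 0
    case_id: str = "phantom"


@dataclass
class CohortSpec:
    """A cohort of phantoms whose log10(TNR) follows a planted linear model.

    log10(TNR) = beta0 + beta_amplitude * a + beta_corr * c + eps, where a
    and c are the per-case texture amplitude and correlation length mapped
    linearly to [-1, 1] over their sampling ranges and eps ~ N(0, noise_sd).
    Defaults keep TNR within [1.5, 6] with a median near 3.3.
    """

    n_cases: int = 40
    base: PhantomSpec = field(default_factory=PhantomSpec)
    amplitude_range: tuple[float, float] = (0.1, 0.5)
    corr_mm_range: tuple[float, float] = (4.0, 10.0)
    beta0: float = math.log10(3.26)
    beta_amplitude: float = 0.15
    beta_corr: float = 0.08
    noise_sd: float = 0.02
    seed: int = 0


def _hotspot_edge(spec: PhantomSpec) -> int:
    vv = float(np.prod(spec.spacing))
    return max(1, int(round((1000.0 / vv) ** (1.0 / 3.0))))


def _tumor_mask(spec: PhantomSpec) -> np.ndarray:
    center = spec.tumor_center_mm
    if center is None:
        center = tuple(n * s / 2.0 for n, s in zip(spec.shape, spec.spacing))
    axes = [np.arange(n) * s + s / 2.0 for n, s in zip(spec.shape, spec.spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    a, b, c = spec.tumor_semi_axes_mm
    cx, cy, cz = center
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 + ((zz - cz) / c) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, TnrResult]:
    """Generate one phantom and its planted ground truth.

    The hottest sub-block is a constant cube of ``hotspot_suv`` at the tumor
    center, and all other tumor voxels are clipped below it, so the
    pipeline's exhaustive window search recovers ``hotspot_suv`` exactly on
    a zero-noise phantom. Fully reproducible from ``spec.seed``.
    """
    if spec.reference_mean <= 0:
        raise ValueError("planted reference mean must be positive")
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape

    vol = rng.normal(spec.background_mean, spec.background_sd, shape)
    np.clip(vol, 0.0, None, out=vol)

    tumor = _tumor_mask(spec)
    if not tumor.any():
        raise ValueError("tumor ellipsoid lies outside the volume")
    if tumor[0].any() or tumor[-1].any() or tumor[:, 0].any() or tumor[:, -1].any() \
            or tumor[:, :, 0].any() or tumor[:, :, -1].any():
        raise ValueError("tumor ellipsoid touches the volume boundary")

    sigma_vox = [spec.texture_corr_mm / s for s in spec.spacing]
    field_noise = gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = field_noise[tumor].std()
    if sd > 0:
        field_noise /= sd
    tumor_vals = spec.tumor_base_suv * (1.0 + spec.texture_amplitude * field_noise[tumor])
    tumor_vals = np.clip(tumor_vals, 0.05 * spec.tumor_base_suv, 0.95 * spec.hotspot_suv)
    vol[tumor] = tumor_vals

    edge = _hotspot_edge(spec)
    center_vox = np.array(np.unravel_index(np.argmax(tumor), shape))
    center_vox = np.array([int(np.mean(idx)) for idx in np.nonzero(tumor)])
    hs_corner = np.clip(center_vox - edge // 2, 0, np.array(shape) - edge)
    hs = tuple(slice(int(c), int(c) + edge) for c in hs_corner)
    vol[hs] = spec.hotspot_suv
    hotspot_region = Region(corner=tuple(int(c) for c in hs_corner),
                            shape=(edge, edge, edge))

    ref = spec.reference_region
    for ax in range(3):
        if ref.corner[ax] < 0 or ref.corner[ax] + ref.shape[ax] > shape[ax]:
            raise ValueError("reference region outside the volume")
    ref_sl = tuple(slice(c, c + s) for c, s in zip(ref.corner, ref.shape))
    if tumor[ref_sl].any():
        raise ValueError("reference region overlaps the tumor")
    ref_vals = spec.reference_mean + rng.normal(0.0, spec.reference_sd, ref.shape) \
        if spec.reference_sd > 0 else np.full(ref.shape, spec.reference_mean)
    vol[ref_sl] = np.clip(ref_vals, 1e-6, None)

    grid = VoxelGrid(values=vol, spacing=spec.spacing, case_id=spec.case_id)
    truth = TnrResult(
        suv_t=spec.hotspot_suv,
        suv_n=spec.reference_mean,
        tnr=spec.hotspot_suv / spec.reference_mean,
        t_region=hotspot_region,
        n_region=ref,
    )
    return grid, truth


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[list[tuple[VoxelGrid, TnrResult]], pd.DataFrame]:
    """Generate a cohort of phantoms realizing the planted TNR model.

    When ``out_dir`` is given, each case is written as ``<case_id>.nii`` plus
    a ``ground_truth.csv`` table. Returns the in-memory cases and the truth
    table (case_id, texture params, planted SUVt/SUVn/TNR).
    """
    rng = np.random.default_rng(spec.seed)
    case_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_cases)
    a_lo, a_hi = spec.amplitude_range
    c_lo, c_hi = spec.corr_mm_range
    cases: list[tuple[VoxelGrid, TnrResult]] = []
    rows = []
    for i in range(spec.n_cases):
        amp = rng.uniform(a_lo, a_hi)
        corr = rng.uniform(c_lo, c_hi)
        a_std = (2.0 * (amp - a_lo) / (a_hi - a_lo)) - 1.0
        c_std = (2.0 * (corr - c_lo) / (c_hi - c_lo)) - 1.0
        eps = rng.normal(0.0, spec.noise_sd)
        log_tnr = spec.beta0 + spec.beta_amplitude * a_std + spec.beta_corr * c_std + eps
        tnr = 10.0 ** log_tnr
        if tnr <= 0:
            raise ValueError("planted model produced non-positive TNR")
        hotspot = tnr * spec.base.reference_mean
        case_id = f"case_{i:03d}"
        pspec = replace(
            spec.base,
            texture_amplitude=amp,
            texture_corr_mm=corr,
            hotspot_suv=hotspot,
            tumor_base_suv=0.55 * hotspot,
            seed=int(case_seeds[i].generate_state(1)[0]),
            case_id=case_id,
        )
        grid, truth = generate_phantom(pspec)
        cases.append((grid, truth))
        rows.append({
            "case_id": case_id,
            "texture_amplitude": amp,
            "texture_corr_mm": corr,
            "suv_t": truth.suv_t,
            "suv_n": truth.suv_n,
            "tnr": truth.tnr,
        })
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for grid, _ in cases:
            write_nifti(grid, out_dir / f"{grid.case_id}.nii")
        table.to_csv(out_dir / "ground_truth.csv", index=False)
    return cases, table


def make_regression_cohort(
    n_cases: int = 40,
    n_features: int = 50,
    n_informative: int = 10,
    beta: float = 0.06,
    noise_sd: float = 0.03,
    beta0: float = math.log10(3.26),
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Tabular cohort with planted linear drivers of log10(TNR).

    Standard-normal features ``f_0001..f_<n>``; the first ``n_informative``
    carry coefficient ``beta`` on the log10(TNR) scale. Used to exercise the
    stability protocol at sizes where image extraction would be wasteful.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_cases, n_features))
    cols = [f"f_{k + 1:04d}" for k in range(n_features)]
    informative = cols[:n_informative]
    log_tnr = beta0 + x[:, :n_informative].sum(axis=1) * beta \
        + rng.normal(0.0, noise_sd, n_cases)
    tnr = 10.0 ** log_tnr
    features = pd.DataFrame(x, columns=cols,
                            index=[f"case_{i:03d}" for i in range(n_cases)])
    return features, tnr, {"informative": informative, "beta": beta}
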