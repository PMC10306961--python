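"""Frozen feature registry and per-case extraction.

The filter/model stages and all tests depend on a stable feature namespace,
so extraction only ever emits ids enumerated here, in this order:

* first-order block on the original values (``__orig``);
* per discretization scheme: co-occurrence and run-length statistics
  (``__<scheme>_b<L>_d1_mean``) and the geometric block
  (``fractal_bc_d_<g>`` / ``fractal_c_d_<g>`` for g = 1..L, plus
  volume/surface at the reference level, ``__<scheme>_<L>``).
"""

from __future__ import annotations

import numpy as np

from .discretize import SCHEMES, discretize
from .features.cooccurrence import GLCM_STAT_IDS, GLRLM_STAT_IDS, cooccurrence_feature_block
from .features.firstorder import FIRST_ORDER_IDS, first_order_features
from .features.geometric import GEOM_EXTRA_IDS, geometric_feature_block
from .image_model import VoxelGrid

__all__ = ["feature_ids", "extract_case"]


def feature_ids(levels: int = 128, schemes: tuple[str, ...] = SCHEMES) -> list[str]:
    """The frozen, ordered list of feature ids for a given configuration."""
    ids: list[str] = list(FIRST_ORDER_IDS)
    for scheme in schemes:
        cooc = f"__{scheme}_b{levels}_d1_mean"
        ids.extend(k + cooc for k in GLCM_STAT_IDS)
        ids.extend(k + cooc for k in GLRLM_STAT_IDS)
        geom = f"__{scheme}_{levels}"
        ids.extend(f"fractal_bc_d_{g}{geom}" for g in range(1, levels + 1))
        ids.extend(f"fractal_c_d_{g}{geom}" for g in range(1, levels + 1))
        ids.extend(k + geom for k in GEOM_EXTRA_IDS)
    return ids


def extract_case(
    grid: VoxelGrid,
    levels: int = 128,
    schemes: tuple[str, ...] = SCHEMES,
    corrdim_max_points: int = 2000,
) -> dict[str, float]:
    """Extract the full registered feature vector for one case.

    Returns feature-id -> value in registry order; any id the feature code
    emits that is not in the registry is a programming error and raises.
    """
    values: dict[str, float] = dict(first_order_features(grid))
    for scheme in schemes:
        disc = discretize(grid, scheme, levels)
        values.update(cooccurrence_feature_block(disc))
        values.update(geometric_feature_block(disc, corrdim_max_points=corrdim_max_points))
    registry = feature_ids(levels, schemes)
    unknown = set(values) - set(registry)
    if unknown:
        raise RuntimeError(f"features outside the frozen registry: {sorted(unknown)}")
    return {fid: values.get(fid, float("nan")) for fid in registry}
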