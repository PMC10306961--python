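"""First-order (histogram) statistics of the SUV distribution.

Computed on the original, non-discretized volume; feature ids carry the
``__orig`` suffix. Conventions frozen here so every downstream oracle agrees:

* standard deviation and the moment statistics use the population (biased)
  estimators; kurtosis is reported as excess kurtosis;
* the mode of continuous data is the modal bin center of the equal-size
  L-level histogram (default L=128), ties broken toward the lowest bin;
* entropy is Shannon entropy (base 2) of the same histogram;
* ``Max_AD_md`` is the maximum absolute deviation from the median.

Zero-variance inputs yield NaN for skewness and kurtosis (missing), not an
error.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..image_model import VoxelGrid

__all__ = ["first_order_features", "FIRST_ORDER_IDS"]

FIRST_ORDER_IDS = (
    "Mean__orig",
    "Median__orig",
    "Mode__orig",
    "SD__orig",
    "Min__orig",
    "Max__orig",
    "Range__orig",
    "Skewness__orig",
    "Kurtosis__orig",
    "Energy__orig",
    "Entropy__orig",
    "Max_AD_md__orig",
)


def first_order_features(grid: VoxelGrid, hist_levels: int = 128) -> dict[str, float]:
    """First-order statistics of the voxel-value distribution.

    Returns an ordered mapping feature-id -> value with ids from
    :data:`FIRST_ORDER_IDS`. Missing values are NaN.
    """
    x = grid.values.ravel().astype(np.float64)
    if x.size == 0:
        raise ValueError("empty grid")
    mn = float(x.min())
    mx = float(x.max())
    med = float(np.median(x))

    if mx == mn:
        # exact zero dispersion on constant input, not float dust
        sd = 0.0
        mode = mn
        entropy = 0.0
        skew = float("nan")
        kurt = float("nan")
    else:
        sd = float(x.std(ddof=0))
        counts, edges = np.histogram(x, bins=hist_levels, range=(mn, mx))
        k = int(np.argmax(counts))  # argmax returns the first (lowest) modal bin
        mode = float(0.5 * (edges[k] + edges[k + 1]))
        p = counts[counts > 0] / x.size
        entropy = float(-np.sum(p * np.log2(p)))
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))

    return {
        "Mean__orig": float(x.mean()),
        "Median__orig": med,
        "Mode__orig": mode,
        "SD__orig": sd,
        "Min__orig": mn,
        "Max__orig": mx,
        "Range__orig": mx - mn,
        "Skewness__orig": skew,
        "Kurtosis__orig": kurt,
        "Energy__orig": float(np.sum(x * x)),
        "Entropy__orig": entropy,
        "Max_AD_md__orig": float(np.max(np.abs(x - med))),
    }
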