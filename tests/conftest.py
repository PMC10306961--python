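from __future__ import annotations

import numpy as np
import pytest

from petrad.discretize import DiscretizedImage
from petrad.image_model import VoxelGrid
from petrad.synthetic import PhantomSpec, generate_phantom


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid(rng) -> VoxelGrid:
    return VoxelGrid(values=rng.uniform(0.5, 8.0, (6, 5, 4)), spacing=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def default_phantom():
    """Default phantom and its planted ground truth (session-cached)."""
    return generate_phantom(PhantomSpec(seed=7))


def make_disc(levels: np.ndarray, L: int, scheme: str = "es",
              spacing=(1.0, 1.0, 1.0)) -> DiscretizedImage:
    """Wrap a raw integer level array as a DiscretizedImage for feature tests."""
    lv = np.asarray(levels, dtype=np.int32)
    if lv.ndim == 1:
        lv = lv.reshape(-1, 1, 1)
    return DiscretizedImage(
        levels=lv, L=L, scheme=scheme,
        bin_edges=np.arange(L + 1, dtype=np.float64), spacing=spacing,
    )
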