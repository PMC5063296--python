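import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from phantex.texture import GreyLevelImage  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20160164)


def random_masked_grey(rng, shape=(4, 4, 4), n_levels=4, p_mask=0.85):
    """Random small grey-level grid with a random (non-trivial) mask."""
    while True:
        mask = rng.random(shape) < p_mask
        if mask.sum() >= 4:
            break
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return GreyLevelImage(levels=levels, mask=mask, n_levels=n_levels, vmin=0.0, vmax=1.0)


@pytest.fixture
def strip():
    """A 3-voxel 1D strip with levels [1, 1, 2] (single pair direction)."""
    levels = np.array([1, 1, 2], dtype=np.int32).reshape(3, 1, 1)
    return GreyLevelImage(
        levels=levels, mask=np.ones((3, 1, 1), bool), n_levels=64, vmin=0.0, vmax=1.0
    )
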