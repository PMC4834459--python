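import numpy as np
import pytest

from ppimlda.synthetic import SimConfig, make_gray_matter_map
from ppimlda.volume import VolumeGrid, default_affine


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """10 x 12 x 10 grid, 2.29 x 2.29 x 3 mm voxels, world origin at center."""
    return SimConfig(grid_shape=(10, 12, 10)).make_grid()


@pytest.fixture
def small_config():
    return SimConfig(
        grid_shape=(10, 12, 10),
        n_patients=6,
        n_controls=5,
        signal_fraction=0.02,
        rng_seed=42,
    )


@pytest.fixture
def gm_and_mask(small_config):
    gm = make_gray_matter_map(small_config.make_grid(), rng_seed=7)
    return gm, gm.data > 0.25


def mask_feature_vector(volume, mask):
    """Reference masked feature extraction in the documented x-fastest order."""
    return volume.ravel(order="F")[np.flatnonzero(mask.ravel(order="F"))]
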