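import numpy as np
import pytest

from nbstab import VolumeGrid, VoxelMask


@pytest.fixture
def small_grid() -> VolumeGrid:
    return VolumeGrid.isotropic((4, 3, 2))


@pytest.fixture
def full_mask(small_grid) -> VoxelMask:
    return VoxelMask(grid=small_grid, in_mask=np.ones(small_grid.shape, dtype=bool))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
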