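import numpy as np
import pytest

from ablate90.grids import LabelMask, ScalarMap, VoxelGrid


def small_grid(shape=(8, 8, 8), spacing=2.0, origin=(0.0, 0.0, 0.0)) -> VoxelGrid:
    return VoxelGrid(shape, (spacing,) * 3, origin)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160901)


@pytest.fixture
def random_dose(rng) -> ScalarMap:
    grid = small_grid((10, 10, 10))
    return ScalarMap(grid, rng.gamma(2.0, 60.0, size=grid.shape), units="Gy")


@pytest.fixture
def full_mask(random_dose) -> LabelMask:
    return LabelMask(random_dose.grid, np.ones(random_dose.grid.shape, dtype=bool))
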