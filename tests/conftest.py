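import numpy as np
import pytest

from abysshill.grids import BathymetryGrid
from abysshill import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_grid():
    return BathymetryGrid(np.full((20, 20), 4850.0), cell_size=100.0)


@pytest.fixture
def dipping_grid():
    # 1 m per 100 m cell, dipping along x
    depths = 4800.0 + np.arange(20)[None, :] * np.ones((20, 1))
    return BathymetryGrid(depths, cell_size=100.0)


@pytest.fixture
def hill_config():
    """80 m / 1000 m Gaussian hill centred exactly on a cell centre."""
    return syn.GeneratorConfig(
        hills=[syn.HillSpec(center_x=2950.0, center_y=2950.0,
                            height=80.0, radius=1000.0)],
        grid_shape=(60, 60), cell_size=100.0, seed=7,
    )


@pytest.fixture
def hill_grid(hill_config):
    return syn.make_bathymetry(hill_config)
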