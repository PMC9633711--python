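import numpy as np
import pytest

from sdcmap import ReferenceGrid, SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_grid():
    return ReferenceGrid(shape=(16, 16, 16), voxel_size=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(
        n_patients=40,
        n_tracts=4,
        streamlines_per_tract=8,
        planted_tracts=(1, 2),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config, small_grid):
    """A small but complete synthetic study shared across tests."""
    return simulate_study(tiny_config, grid=small_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
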