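import numpy as np
import pytest

from srrmri.phantom import PhantomSpec, make_phantom
from srrmri.volumes import Volume, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return VoxelGrid((24, 24, 24), (0.5, 0.5, 0.5))


@pytest.fixture
def small_volume(small_grid, rng):
    return Volume(small_grid, rng.standard_normal(small_grid.shape))


@pytest.fixture(scope="session")
def phantom48():
    """Noiseless 48^3 phantom at 0.5 mm, shared across tests."""
    grid = VoxelGrid((48, 48, 48), (0.5, 0.5, 0.5))
    return make_phantom(PhantomSpec(grid=grid, geometry_seed=1, noise_sd=0.0))
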