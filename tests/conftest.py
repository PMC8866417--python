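import numpy as np
import pytest

from ambientsom import object_simulator as osim


@pytest.fixture(scope="session")
def lumpy_config():
    """Desk-scale stationary lumpy process (periodic, unnormalized)."""
    return osim.LumpyConfig(grid_size=32, mean_lump_count=60.0,
                            lump_amplitude=1.0, lump_width=1.8)


@pytest.fixture(scope="session")
def big_lumpy_ensemble(lumpy_config):
    """20,000 stationary lumpy samples shared by the Monte Carlo oracles."""
    return osim.make_ensemble(lumpy_config, 20_000, seed=11)


@pytest.fixture(scope="session")
def normalized_lumpy_images():
    """A small [0,1]-normalized lumpy stack (smooth content for noise tests)."""
    cfg = osim.LumpyConfig(grid_size=32, normalize="per_image_minmax")
    return osim.make_ensemble(cfg, 200, seed=5).images


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
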