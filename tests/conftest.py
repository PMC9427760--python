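import numpy as np
import pytest

from ctatrophy.phantom import PhantomParams, generate_phantom, simulate_cohort

# small grids keep the suite fast; geometry properties are resolution-free
SMALL_GRID = (20, 32, 32)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomParams(grid_shape=SMALL_GRID, noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomParams(grid_shape=SMALL_GRID, noise_sd=2.0, seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """Twenty rated subjects on a small grid, mild noise."""
    base = PhantomParams(grid_shape=SMALL_GRID, noise_sd=2.0)
    return simulate_cohort(20, rating_noise=0.05, seed=42, base_params=base)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
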