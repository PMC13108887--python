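import numpy as np
import pytest

from adefield.grid import make_grid
from adefield.model import ModelParams
from adefield.shapes import smooth_random_field
from adefield.verify import tanh_sphere


@pytest.fixture(scope="session")
def grid32():
    return make_grid(1.0, 32)


@pytest.fixture(scope="session")
def grid48():
    return make_grid(1.0, 48)


@pytest.fixture(scope="session")
def grid64():
    return make_grid(1.0, 64)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture()
def smooth_field(grid32, rng):
    """Band-limited random field, |values| <= 0.9."""
    return smooth_random_field(grid32, rng, amplitude=0.9)


@pytest.fixture(scope="session")
def sphere64():
    """Resolved tanh sphere fixture: R=0.35, eps=0.02, N=64."""
    grid = make_grid(1.0, 64)
    params = ModelParams(epsilon=0.02)
    return grid, tanh_sphere(grid, 0.35, 0.02), params
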