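import numpy as np
import pytest

from convspec.device_model import (
    CascadeDesign,
    WavenumberGrid,
    comb_response,
    design_cascade,
    system_response,
)
from convspec.spectra_fixtures import default_grid


@pytest.fixture(scope="session")
def grid() -> WavenumberGrid:
    """Default characterization window: 6250 cm^-1, step 2.1 cm^-1, N=200."""
    return default_grid()


@pytest.fixture(scope="session")
def ternary4(grid) -> CascadeDesign:
    """Default device: ideal 4-stage ternary cascade over the grid span."""
    return design_cascade(4, grid.span, scheme="ternary")


@pytest.fixture(scope="session")
def ternary4_response(ternary4, grid):
    return system_response(ternary4, grid)


@pytest.fixture(scope="session")
def comb78(grid):
    """Tabulated response with contiguous flat components up to k = 78."""
    return comb_response(grid, 78)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
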