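import numpy as np
import pytest

from flimhet.model import TimeGrid, gaussian_irf
from flimhet.synthetic import AcquisitionSpec, acquisition_irf


@pytest.fixture(scope="session")
def acq():
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def grid(acq):
    return acq.grid()


@pytest.fixture(scope="session")
def irf(acq):
    return acquisition_irf(acq)


@pytest.fixture(scope="session")
def coarse_grid():
    """A small grid for cheap exactness checks."""
    return TimeGrid(n_bins=64, bin_width=12.5 / 64, rep_period=12.5)


@pytest.fixture(scope="session")
def coarse_irf(coarse_grid):
    return gaussian_irf(coarse_grid, fwhm=0.3, center=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
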