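import numpy as np
import pytest

from qensmem.instrument import make_resolution
from qensmem.models import EnergyGrid


@pytest.fixture(scope="session")
def grid():
    return EnergyGrid.symmetric(30.0, 0.1)


@pytest.fixture(scope="session")
def kernel(grid):
    return make_resolution(grid, fwhm=0.75)


@pytest.fixture(scope="session")
def tabulated_kernel(kernel):
    """Same Gaussian response, but presented as a tabulated kernel so the
    numerical convolution path is exercised."""
    from qensmem.instrument import ResolutionKernel

    return ResolutionKernel(
        grid=kernel.grid, values=kernel.values, fwhm=kernel.fwhm, gaussian_sd=None
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
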