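import numpy as np
import pytest

from ptcmap.hrf_model import CANONICAL_HRF, double_gamma_kernel
from ptcmap.stimulus_design import build_aperture, make_run_design

# Reduced search grids reused across tests: full-resolution grids are only
# exercised where the printed ranges themselves are under test.
MU_SMALL = np.linspace(-0.2, 1.2, 29)
SIGMA_SMALL = 2.0 ** np.linspace(-5.6, 1.0, 14)


@pytest.fixture(scope="session")
def spatial_design():
    return make_run_design("spatial")


@pytest.fixture(scope="session")
def face_design():
    return make_run_design("face")


@pytest.fixture(scope="session")
def spatial_aperture(spatial_design):
    return build_aperture(spatial_design, n_bins=200)


@pytest.fixture(scope="session")
def face_aperture(face_design):
    return build_aperture(face_design, n_bins=200)


@pytest.fixture(scope="session")
def canonical_kernel():
    return double_gamma_kernel(CANONICAL_HRF, dt=1.0)


@pytest.fixture(scope="session")
def small_grid(spatial_aperture):
    from ptcmap.tuning_fit import prediction_grid

    return prediction_grid(spatial_aperture, MU_SMALL, SIGMA_SMALL)


@pytest.fixture(scope="session")
def full_grid(spatial_aperture):
    from ptcmap.tuning_fit import prediction_grid

    return prediction_grid(spatial_aperture)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
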