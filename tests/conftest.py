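import numpy as np
import pytest

from prmivim.ivim import DEFAULT_BVALUES, BValueScheme, IvimPriors
from prmivim.phantom import CohortParams, make_phantom, simulate_cohort

# Table-1-style tumor-mean parameters used throughout the recovery tests
TRUE_D = 1.07e-3
TRUE_F = 0.127
TRUE_DSTAR = 13.7e-3
TRUE_S0 = 1000.0


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    return BValueScheme(DEFAULT_BVALUES)


@pytest.fixture(scope="session")
def priors() -> IvimPriors:
    return IvimPriors()


@pytest.fixture(scope="session")
def phantom_default():
    """64^3 / 2 mm phantom with a 25 mm spherical tumor (~65 cc)."""
    return make_phantom(seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast 4-patient cohort on coarse grids for pipeline-level tests."""
    params = CohortParams(
        n_patients=4,
        grid_shape=(32, 32, 32),
        voxel_size=(3.5, 3.5, 3.5),
        pet_shape=(30, 30, 30),
        pet_voxel_size=(4.0, 4.0, 4.0),
        gtv_cc_range=(20.0, 80.0),
        gtv_cc_sd=20.0,
        seed=123,
    )
    return simulate_cohort(params)


def rician(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: independent oracle for the generator's model."""
    n1 = rng.normal(0.0, sigma, clean.shape)
    n2 = rng.normal(0.0, sigma, clean.shape)
    return np.sqrt((clean + n1) ** 2 + n2**2)
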