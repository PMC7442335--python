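import numpy as np
import pytest

from gammadcm import default_parameters
from gammadcm.spectral import default_grid, predict_spectrum


@pytest.fixture(scope="session")
def prior_params():
    return default_parameters()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def prior_spectrum(prior_params):
    """Noise-free spectrum generated at the prior means."""
    return predict_spectrum(prior_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def draw_stable_params(rng, sd=0.2, free=(3, 4, 5, 6, 7, 8, 10, 11)):
    """Random parameter set around the priors (free couplings jittered)."""
    p = default_parameters()
    p.gamma[list(free)] = rng.normal(0.0, sd, len(free))
    return p
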