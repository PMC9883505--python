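import numpy as np
import pytest

import shvrestore as sr


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_gaussian_psf():
    return sr.gaussian_psf((7, 7), sigma_xy=1.0)


@pytest.fixture(scope="session")
def spots_64():
    """Clean 64x64 spots phantom shared by selection/pipeline tests."""
    spec = sr.PhantomSpec(kind="spots", shape=(64, 64), n_objects=10, object_scale=1.2, seed=7)
    return sr.make_phantom(spec)


@pytest.fixture(scope="session")
def degraded_64(spots_64):
    """The phantom blurred (sigma_xy = 1) with pure Gaussian noise tau = 0.01."""
    psf = sr.gaussian_psf(sigma_xy=1.0)
    params = sr.DegradationParams(alpha=None, tau=0.01, seed=11)
    return sr.degrade(spots_64, psf, params)
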