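import numpy as np
import pytest
from hypothesis import settings

from pericap import synthetic as sy

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_profile():
    """Noiseless Gaussian line profile with known parameters."""
    return sy.gen_profile(
        sy.ProfileSpec(amplitude=100.0, center_um=0.0, sigma_um=2.0,
                       baseline=10.0, noise_sd=0.0),
        seed=0,
    )


@pytest.fixture
def uniform_stalls():
    return sy.gen_stalls(sy.StallScene(n_stalls=119, mode="uniform"), seed=42)
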