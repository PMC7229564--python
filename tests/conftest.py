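import numpy as np
import pytest

from guanloc import phantom
from guanloc.io import ThermalImage


@pytest.fixture(scope="session")
def noiseless_spec():
    return phantom.PhantomSpec(noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return phantom.generate(noiseless_spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    return phantom.generate(phantom.PhantomSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_image(rng):
    return ThermalImage(rng.uniform(0, 100, size=(32, 32)))
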