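import numpy as np
import pytest

from dixonseg.phantom import PhantomSpec, simulate_dixon_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise- and bias-free phantom spec (analytic checks)."""
    return PhantomSpec(seed=7, noise_sigma=0.0, bias_amplitude=0.0)


@pytest.fixture(scope="session")
def phantom_pair(default_spec):
    return simulate_dixon_phantom(default_spec)


@pytest.fixture(scope="session")
def clean_phantom_pair(clean_spec):
    return simulate_dixon_phantom(clean_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
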