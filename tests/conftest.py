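import numpy as np
import pytest
from hypothesis import settings

import synthmpm as sm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def protocol():
    return sm.default_protocol()


@pytest.fixture(scope="session")
def clean_truth():
    """Noiseless, residual-free, unit-efficiency phantom (32^3)."""
    spec = sm.PhantomSpec(noise_sigma=0.0, residual_sigma=0.0,
                          b1_field_params={"center": 1.0, "radial": 0.0},
                          seed=11)
    return sm.build_phantom(spec)


@pytest.fixture(scope="session")
def clean_session(clean_truth, protocol):
    return sm.simulate_mpm_session(clean_truth, protocol, noise_sigma=0.0, seed=12)


@pytest.fixture(scope="session")
def clean_maps(clean_session):
    return sm.fit_maps(clean_session)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
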