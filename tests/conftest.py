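import numpy as np
import pytest
from hypothesis import settings

from gpderank import SEHyperparams, TimeCourseProfile

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_profile(rng, n, probe_id="p"):
    """Small random profile with repeated times allowed."""
    t = np.sort(rng.uniform(0, 10, size=n))
    y = rng.normal(0, 1, size=n)
    return TimeCourseProfile(probe_id, t, y)


def random_hyperparams(rng):
    return SEHyperparams(
        lengthscale_sq=float(rng.uniform(0.3, 30.0)),
        signal_variance=float(rng.uniform(0.05, 3.0)),
        noise_variance=float(rng.uniform(0.05, 2.0)),
    )


@pytest.fixture
def profile_factory():
    return random_profile


@pytest.fixture
def hyp_factory():
    return random_hyperparams
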