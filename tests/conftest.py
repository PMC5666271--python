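import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ontotraj import CANONICAL_VARIABLES
from ontotraj.synthetic import DEFAULT_EXPONENTS, SyntheticSpec, generate_series

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Analysis warnings (small n, normality advisories) are expected in
    synthetic runs and would drown real signal."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def doglike_exponents():
    """Balanced mixed-allometry exponent vector (mean exactly 1)."""
    return np.array([DEFAULT_EXPONENTS[v] for v in CANONICAL_VARIABLES])


@pytest.fixture
def isometric_series():
    """Noise-free isometric series: every variable a common multiple of a
    single latent size factor."""
    spec = SyntheticSpec(form="wild", n=20, exponents=1.0, noise_sd=0.0, seed=11)
    return generate_series(spec, "iso", "pair01")


@pytest.fixture
def doglike_series(doglike_exponents):
    """Mixed positive/negative allometry, moderate noise, 40 specimens."""
    spec = SyntheticSpec(form="wild", n=40, exponents=doglike_exponents,
                         noise_sd=0.02, seed=12)
    return generate_series(spec, "doglike", "pair01")


@pytest.fixture
def small_series(doglike_exponents):
    """12-specimen series for brute-force jackknife oracles."""
    spec = SyntheticSpec(form="wild", n=12, exponents=doglike_exponents,
                         noise_sd=0.05, seed=13)
    return generate_series(spec, "small", "pair01")
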