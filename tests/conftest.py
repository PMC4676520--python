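import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tfdmi import BindingModel, SelectionParams

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def model10():
    """Default binding model: ell=10, deps=3 kBT, deps_ns=1.5 kBT, r*=5."""
    return BindingModel(ell=10)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def scaled(size, Ne=1000.0, mu0=1.0):
    return SelectionParams.from_scaled(size, Ne=Ne, mu0=mu0)
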