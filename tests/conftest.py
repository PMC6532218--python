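import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ihczone import CoreSpec, Pattern, render_core

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mixed_core():
    """One noise-free mixed-pattern core shared across tests."""
    spec = CoreSpec(seed=11, noise_sd=0.0, pattern=Pattern.MIXED,
                    target_positive_fraction=0.15)
    return render_core(spec)


@pytest.fixture(scope="session")
def interterritorial_core():
    spec = CoreSpec(seed=7, noise_sd=0.0, pattern=Pattern.INTERTERRITORIAL,
                    target_positive_fraction=0.2)
    return render_core(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
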