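import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_spectra():
    """The default 142-sample synthetic study, generated once per session."""
    from nirdd.synthetic import simulate_study

    return simulate_study(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
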