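import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny synthetic cohort shared by structural tests."""
    from footsga import SynthConfig, generate_cohort

    cfg = SynthConfig(
        n_pd=3, n_control=3, recording_minutes=0.6, sampling_rate=200.0, seed=7
    )
    return generate_cohort(cfg)
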