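import pytest
from hypothesis import HealthCheck, settings

from petquant.simulate import InputSpec, brain_schedule

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Package-wide seed convention for stochastic tests.
SEED = 0


@pytest.fixture(scope="session")
def input_truth():
    """Noise-free arterial input function with the default bolus shape."""
    return InputSpec().truth()


@pytest.fixture(scope="session")
def schedule():
    """The 31-frame, 120-min acquisition schedule."""
    return brain_schedule()
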