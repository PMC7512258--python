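import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_series():
    """The hand-checkable worked example: b=4, a=2 at m=1, r=0.5."""
    from sampen import TimeSeries

    return TimeSeries(np.array([1.0, 2.0, 1.0, 2.0, 1.0, 3.0]))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
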