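import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cosine24():
    """Noiseless 24-hr cosine on the canonical 12-point, 4-hr grid."""
    from circadia import CircadianSeries

    t = np.arange(12) * 4.0
    return CircadianSeries(t0_ct_hr=14.0, dt_hr=4.0, values=np.cos(2 * np.pi * t / 24.0))
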