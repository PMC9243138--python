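import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from noxtact import SpikeTrain, make_heat_trace

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def poisson_train(rng, rate_hz: float, duration_s: float, **kw) -> SpikeTrain:
    n = rng.poisson(rate_hz * duration_s)
    t = np.sort(rng.uniform(0.0, duration_s, n))
    kw.setdefault("unit_id", "u0")
    kw.setdefault("region", "Dys")
    kw.setdefault("layer", "L2/3")
    kw.setdefault("kind", "SUA")
    return SpikeTrain(spike_times=t, **kw)


@pytest.fixture(scope="session")
def heat_trace():
    return make_heat_trace()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
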