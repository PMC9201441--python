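import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dibs.coherence import WaveletSpec
from dibs.synthgen import SimConfig, default_state_topologies

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: short session plan used by most unit tests (full-length plans are reserved
#: for the recovery suites, which need the statistical power)
SHORT_PLAN = (("rest", 60.0), ("taskA", 150.0), ("taskB", 150.0), ("rest", 30.0))


@pytest.fixture(scope="session")
def spec10() -> WaveletSpec:
    return WaveletSpec(sampling_rate=10.0)


@pytest.fixture()
def small_cfg() -> SimConfig:
    return SimConfig(
        n_rois=4,
        session_plan=SHORT_PLAN,
        coupling_strength=default_state_topologies(3, 4),
        seed=42,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    # fresh per test: keeps results independent of test execution order
    return np.random.default_rng(20240917)
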