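import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaitphase import GaitProfileParams, GcfRecording, StttaParams, generate_walk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_params() -> StttaParams:
    return StttaParams()


@pytest.fixture(scope="session")
def clean_walk():
    """Noise-free default walk: 10 s at 2000 Hz, 10 gait cycles."""
    params = GaitProfileParams(noise_sd=0.0)
    ball, heel, truth = generate_walk(params, duration_s=10.0, fs=2000.0)
    return params, ball, heel, truth


@pytest.fixture
def square_wave() -> GcfRecording:
    """500 N for 0.6 s / 0 N for 0.4 s at 1000 Hz, three cycles."""
    f = np.array(([500.0] * 600 + [0.0] * 400) * 3)
    return GcfRecording.from_force(f, fs=1000.0, channel="ball")
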