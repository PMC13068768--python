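import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gazebench import GazeRecording

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_recording(x, y=None, rate=500.0):
    """Build a recording from position arrays at a given rate."""
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    t = np.arange(x.size) * (1000.0 / rate)
    return GazeRecording(t=t, x=x, y=y, sampling_rate=rate)


@pytest.fixture
def still_recording():
    """1000 samples of perfectly stationary gaze at 500 Hz."""
    return make_recording(np.full(1000, 3.0), np.full(1000, -1.5))
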