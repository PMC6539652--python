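import numpy as np
import pandas as pd
import pytest

from accelband.recording import RawRecording
from accelband.synthetic import GaitModel, SubjectProfile


@pytest.fixture(scope="session")
def adult_profile():
    return SubjectProfile.default("adult")


@pytest.fixture(scope="session")
def child_profile():
    return SubjectProfile.default("child")


def tone_recording(freq_hz, amp_g, duration_s=60.0, rate_hz=30.0, axis=0,
                   gravity=True, start="2023-05-01 08:00:00"):
    """Single-axis sinusoid, optionally riding on 1 g vertical gravity."""
    n = int(duration_s * rate_hz)
    t = np.arange(n) / rate_hz
    x = np.zeros((n, 3))
    if gravity:
        x[:, 0] = 1.0
    x[:, axis] += amp_g * np.sin(2 * np.pi * freq_hz * t)
    return RawRecording(start_time=pd.Timestamp(start), sample_rate=rate_hz,
                        samples=x, dynamic_range=8.0)


@pytest.fixture
def tone():
    return tone_recording


@pytest.fixture
def gait_recording(adult_profile):
    """Two minutes of broadband synthetic gait at 5 km/h, 30 Hz."""
    from accelband.synthetic import gen_locomotion_signal

    model = adult_profile.gait_model(5.0, 30.0)
    return gen_locomotion_signal(model, 120.0, 30.0, seed=7, dynamic_range=6.0)
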