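import numpy as np
import pytest

from quatresp.simulate import Scenario, simulate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_unit_quaternions(rng, n):
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


@pytest.fixture(scope="session")
def static_recording():
    """A 300 s sitting recording breathing at 15 breaths/min, no dropouts."""
    s = Scenario(activity="sitting_no_support", rr_true=15.0, seed=3, dropout_rate=0.0)
    rec, truth = simulate_recording(s)
    return rec, truth


def sinusoid(freq_hz, duration_s, fs=10.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(round(duration_s * fs))) / fs
    return t, amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
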