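import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from limbuse.detection import DetectorParams
from limbuse.io import AccelTrace

FS = 100.0


def make_trace(data, fs=FS, limb="intact"):
    return AccelTrace(data=np.asarray(data, dtype=float), sample_rate=fs, limb_label=limb)


def burst_trace(duration_s=10.0, bursts=(), noise_sd=0.0, offset=(0.0, 0.0, 0.0),
                fs=FS, rng=None):
    """Trace with single-cycle sinusoidal bursts: each burst is
    (onset_s, duration_s, peak_to_peak, axis)."""
    n = int(round(duration_s * fs))
    rng = rng or np.random.default_rng(0)
    data = np.asarray(offset, float) + (rng.normal(0, noise_sd, (n, 3)) if noise_sd else np.zeros((n, 3)))
    for onset_s, dur_s, amp, axis in bursts:
        s = int(round(onset_s * fs))
        m = int(round(dur_s * fs))
        data[s : s + m, axis] += 0.5 * amp * np.sin(2 * np.pi * np.arange(m) / m)
    return make_trace(data)


def random_trace(rng, fs=FS):
    """Randomised trace for oracle-equivalence checks: noisy baseline with a
    random number of bursts of amplitudes straddling the detection
    threshold, random durations and arbitrary (possibly colliding)
    placement."""
    duration = rng.uniform(4.0, 9.0)
    n = int(round(duration * fs))
    data = rng.uniform(-0.5, 0.5, 3) + rng.normal(0, rng.uniform(0.0, 0.06), (n, 3))
    for _ in range(rng.integers(0, 6)):
        m = int(rng.uniform(0.1, 0.8) * fs)
        s = int(rng.integers(0, max(1, n - m)))
        amp = rng.uniform(0.05, 0.7)
        axis = int(rng.integers(0, 3))
        data[s : s + m, axis] += 0.5 * amp * np.sin(2 * np.pi * np.arange(m) / m)
    return make_trace(data)


@pytest.fixture
def params():
    return DetectorParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
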