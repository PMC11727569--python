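import numpy as np
import pytest

from myogest.preprocessing import RawRecording
from myogest.synthetic import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def small_recording() -> RawRecording:
    """Short, fast 3-class 4-channel recording for unit tests."""
    cfg = SynthConfig(n_classes=3, T=4, f=1000.0, reps=2,
                      active_s=1.0, rest_s=0.5, seed=7)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def smoke_config() -> SynthConfig:
    """The desk-scale learning benchmark: 4 separable classes, 8 channels,
    5 repetitions at the standard 5 s active / 3 s rest protocol."""
    return SynthConfig(n_classes=4, T=8, f=1000.0, reps=5,
                       active_s=5.0, rest_s=3.0, snr_db=35.0, seed=11)


def numeric_grad(fn, arrays, which, eps=1e-6):
    """Central-difference gradient of scalar fn(arrays) w.r.t. arrays[which]."""
    base = [a.copy() for a in arrays]
    g = np.zeros_like(base[which])
    for idx in np.ndindex(base[which].shape):
        plus = [a.copy() for a in base]
        plus[which][idx] += eps
        minus = [a.copy() for a in base]
        minus[which][idx] -= eps
        g[idx] = (fn(plus) - fn(minus)) / (2 * eps)
    return g
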