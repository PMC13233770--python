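import numpy as np
import pytest

from cionakit.bodyplan import default_body_plan
from cionakit.synthetic import SynthConfig, simulate_recording


@pytest.fixture(scope="session")
def plan():
    return default_body_plan()


@pytest.fixture(scope="session")
def quiet_recording():
    """Short noise-free, event-free, dropout-free recording (static-ish)."""
    cfg = SynthConfig(n_frames=400, seed=5, noise_sd=0.0, dropout_rate=0.0,
                      background_sd=(0.0, 0.0, 0.0, 0.0, 0.0))
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def reference_recording():
    """One default-condition recording with ground truth (15 min, 20 Hz)."""
    cfg = SynthConfig(n_frames=6000, seed=11)
    return simulate_recording(cfg)
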