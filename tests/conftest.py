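import warnings

import numpy as np
import pytest

import hfokit as hk

# epoch warnings (signal shorter than one detector epoch) are expected on
# the short fixtures used throughout
warnings.filterwarnings("ignore", message="signal shorter than one epoch")


@pytest.fixture(scope="session")
def sim_recording():
    """Default-condition synthetic recording with ground truth (4 x 60 s)."""
    return hk.simulate_recording(hk.SimConfig(seed=1))


@pytest.fixture(scope="session")
def noise_recording():
    """Matched noise-only recording (no injected events)."""
    rec, _ = hk.simulate_recording(hk.SimConfig(seed=1, n_hfo=0))
    return rec


@pytest.fixture()
def small_recording():
    """Tiny deterministic two-channel recording for I/O and feature tests."""
    rng = np.random.default_rng(0)
    fs = 2000.0
    t = np.arange(int(4 * fs)) / fs
    a = 40.0 * np.sin(2 * np.pi * 10.0 * t)
    b = rng.standard_normal(t.size) * 5.0
    return hk.from_array(np.stack([a, b]), fs, ["A1", "A2"])
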