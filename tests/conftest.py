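import numpy as np
import pytest

from gripsense.sim import SimConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def rest_session():
    """60 s rest-only session with target MDF 100 Hz, no drift."""
    cfg = SimConfig(duration_s=60.0, target_mdf_hz=100.0, event_onsets_s=[], seed=7)
    recording, truth = generate_session(cfg)
    return cfg, recording, truth


@pytest.fixture
def burst_session():
    """125 s session with 24 evenly spaced bursts at gain 5."""
    onsets = list(np.arange(2.0, 120.0, 5.0))
    cfg = SimConfig(
        duration_s=125.0, event_onsets_s=onsets, burst_gain=5.0,
        burst_duration_s=1.0, seed=3,
    )
    recording, truth = generate_session(cfg)
    return cfg, recording, truth
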