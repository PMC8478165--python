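import numpy as np
import pandas as pd
import pytest

from cspike.synth import NeuronTuning, SessionConfig, simulate_session


def quiet_tuning(**kw) -> NeuronTuning:
    """Tuning with every task-locked component switched off."""
    base = dict(burst_gain_preferred=0.0, burst_gain_anti=0.0,
                amplitude_slope=0.0, error_tonic_gain=0.0,
                corrective_burst_gain=0.0, trial_onset_gain=0.0,
                suppression_depth=0.0, spikelet_prob_gain=0.0,
                spikelet_base_prob=0.0)
    base.update(kw)
    return NeuronTuning(**base)


@pytest.fixture(scope="session")
def small_session():
    """A 60-trial session with default tuning, shared across tests."""
    cfg = SessionConfig(n_trials=60, seed=42)
    return simulate_session(cfg, NeuronTuning())


@pytest.fixture
def synthetic_events():
    """Hand-built labeled event table (synthetic stand-in for detection)."""
    return pd.DataFrame({
        "onset": [1000.0, 2000.0, 3000.0, 4000.0],
        "offset": [1040.0, 2040.0, 3040.0, 4040.0],
        "amplitude": [15.0, 14.5, 15.5, 15.2],
        "duration": [40.0] * 4,
        "peak_velocity": [700.0, 680.0, 710.0, 705.0],
        "direction": [1, -1, 1, -1],
        "type": ["primary"] * 4,
        "subtype": ["CF", "CP", "CF", "CP"],
        "start_pos": [0.0, 15.0, 0.0, 15.0],
        "end_pos": [15.0, 0.5, 15.5, -0.2],
        "signed_error": [0.0, -0.5, -0.5, 0.2],
        "assoc_trial": [0, 1, 1, 2],
    })
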