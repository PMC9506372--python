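import numpy as np
import pandas as pd
import pytest

from itfx.io import EpochSet, Recording
from itfx.simulate import SimulationParams, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """One reduced synthetic session shared across tests (cheap to extract)."""
    params = SimulationParams(seed=7, theta_freq_hz=5.5, burst_snr=3.0,
                              n_pairs=18, hit_rate=0.9,
                              burst_duration_ms=1000.0, burst_jitter_sd_ms=0.0)
    recording, events, behavior, truth = simulate_session(params)
    return recording, events, behavior, truth


@pytest.fixture
def toy_recording():
    """Four-channel constant-plus-tone recording, 30 s at 500 Hz."""
    fs = 500.0
    t = np.arange(int(30 * fs)) / fs
    data = np.stack([
        np.sin(2 * np.pi * 5.0 * t),
        np.full_like(t, 5.0),
        np.sin(2 * np.pi * 50.0 * t),
        np.zeros_like(t),
    ]) * 10.0
    return Recording(data, fs, ["Cz", "Pz", "C3", "C4"])


def tone_epochs(freq_hz, fs=500.0, n_trials=1, amp=1.0, channel="Cz"):
    """Single-channel pure-tone EpochSet on the standard epoch clock."""
    n = int(round(3500.0 * fs / 1000.0))
    t = np.arange(n) / fs - 1.0
    sig = amp * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(sig, (n_trials, 1, 1))
    return EpochSet(data.copy(), fs, [channel])


def toy_task_tables(n_pairs=4, responses=None):
    """Tiny encoding/recognition task with hand-settable responses.

    ``responses`` maps pair index -> response for the intact (old) probe of
    that pair; defaults to all correct.
    """
    responses = responses or {}
    enc = [{"onset_ms": 2000.0 + 4000.0 * i, "block": "encoding",
            "trial_id": f"enc{i}", "pair_id": f"P{i}"} for i in range(n_pairs)]
    rec, beh = [], []
    t = 2000.0 + 4000.0 * n_pairs + 5000.0
    for i in range(n_pairs):
        rec.append({"onset_ms": t, "block": "recognition",
                    "trial_id": f"old{i}", "pair_id": f"P{i}"})
        beh.append({"trial_id": f"old{i}", "truth": "old",
                    "response": responses.get(i, "old")})
        t += 3000.0
    for i in range(n_pairs):
        rec.append({"onset_ms": t, "block": "recognition",
                    "trial_id": f"rcb{i}", "pair_id": f"P{i}+P{(i + 1) % n_pairs}"})
        beh.append({"trial_id": f"rcb{i}", "truth": "recombined",
                    "response": "recombined"})
        t += 3000.0
    return pd.DataFrame(enc + rec), pd.DataFrame(beh)
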