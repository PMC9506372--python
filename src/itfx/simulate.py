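"""Synthetic EEG sessions with the statistical structure the method assumes.

A simulated session consists of (a) 1/f background noise on every channel,
(b) a continuous posterior alpha rhythm (strongest over PO7/PO8/Oz), and
(c) Hann-windowed theta bursts of known frequency, latency and amplitude,
time-locked (with truncated-Gaussian jitter) to the onsets of the encoding
trials that will later be judged "old" — encoding the assumption that
event-related theta marks successful associative encoding.  Unsuccessful
trials receive no burst.  Burst phase is randomized per trial, the
conservative case for power-based detection.

Burst amplitude is calibrated empirically against the background: the
generator measures the wavelet power of the noise-plus-alpha background at
the burst frequency and the peak wavelet power of a unit-amplitude burst, and
scales the burst so that (burst power)/(background power) equals
``burst_snr``.  The session's ground truth (planted frequency, successful
trial set, burst centers) is returned alongside the data.

EEG is synthesized for the encoding block; recognition-trial onsets continue
in the event table beyond the recorded span, since the method never analyzes
recognition-phase EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import STANDARD_CHANNELS, Recording
from .tfr import morlet_wavelet

CENTROPARIETAL = ("Cz", "C3", "C4", "Pz", "P3", "P4")
POSTERIOR = ("PO7", "PO8", "Oz")
PARIETAL_RING = ("Pz", "P3", "P4", "CP5", "CP6")


@dataclass
class SimulationParams:
    """Generation parameters for one synthetic session.

    Defaults reproduce the task design this package targets: 42 face-scene
    pairs at 500 Hz, 2000 ms stimuli with 1250-1750 ms inter-stimulus
    intervals, a hit rate of 0.6 (about 25 successfully encoded trials) and a
    correct-rejection rate of 0.68 (overall accuracy near 64%).  Bursts
    default to 5.5 Hz at three times the background theta power, lasting
    1000 ms — long enough that the planted frequency is actually defined at
    the 0.5 Hz analysis resolution (shorter Hann bursts are spectrally too
    broad); at that duration the jitter truncation (bursts stay inside the
    scanned 250-1250 ms) pins the burst to the window.
    """

    fs: float = 500.0
    n_pairs: int = 42
    theta_freq_hz: float = 5.5
    burst_onset_ms: float = 450.0
    burst_jitter_sd_ms: float = 75.0
    burst_duration_ms: float = 1000.0
    burst_snr: float = 3.0
    alpha_freq_hz: float = 10.0
    alpha_amp_uv: float = 6.0
    noise_exponent: float = 1.0
    noise_rms_uv: float = 10.0
    hit_rate: float = 0.6
    cr_rate: float = 0.68
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hit_rate <= 1:
            raise ValueError("hit_rate must lie in (0, 1]")
        if self.hit_rate * self.n_pairs < 1:
            raise ValueError("hit_rate * n_pairs must be at least 1")
        grid = round(self.theta_freq_hz * 2) / 2
        if abs(grid - self.theta_freq_hz) > 1e-9 or not 4.0 <= self.theta_freq_hz <= 7.5:
            raise ValueError("theta_freq_hz must lie on the 0.5 Hz grid in [4.0, 7.5]")


@dataclass
class SessionTruth:
    """Ground truth of a simulated session, for parameter-recovery tests."""

    theta_freq_hz: float
    successful_trial_ids: list
    burst_centers_ms: dict
    params: dict = field(default_factory=dict)


def one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                     fs: float, exponent: float, rms_uv: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    freqs[0] = freqs[1]  # avoid the DC singularity
    spec *= freqs ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    x *= rms_uv / x.std(axis=-1, keepdims=True)
    return x


def _alpha_gain(label: str) -> float:
    if label in POSTERIOR:
        return 1.0
    if label in PARIETAL_RING:
        return 0.4
    return 0.1


def _background(rng, labels, n_samples, p: SimulationParams) -> np.ndarray:
    data = one_over_f_noise(rng, len(labels), n_samples, p.fs,
                            p.noise_exponent, p.noise_rms_uv)
    t = np.arange(n_samples) / p.fs
    for i, lab in enumerate(labels):
        phase = rng.uniform(0, 2 * np.pi)
        data[i] += p.alpha_amp_uv * _alpha_gain(lab) * np.sin(
            2 * np.pi * p.alpha_freq_hz * t + phase)
    return data


def _burst_amplitude(rng, p: SimulationParams) -> float:
    """Calibrate the burst peak amplitude to the requested power SNR.

    Background power at the burst frequency is measured on a 30 s probe of
    noise-plus-alpha with centroparietal alpha gain; the gain of a
    unit-amplitude Hann burst through the same wavelet gives the burst-side
    scale.
    """
    fs = p.fs
    probe_n = int(30 * fs)
    probe = one_over_f_noise(rng, 1, probe_n, fs, p.noise_exponent, p.noise_rms_uv)[0]
    t = np.arange(probe_n) / fs
    probe += p.alpha_amp_uv * 0.4 * np.sin(2 * np.pi * p.alpha_freq_hz * t)
    w = morlet_wavelet(p.theta_freq_hz, fs)
    half = (len(w) - 1) // 2
    conv = np.convolve(probe, w, mode="same")
    p_bg = float(np.mean(np.abs(conv[half:-half]) ** 2))

    n_burst = int(round(p.burst_duration_ms * fs / 1000.0))
    burst = np.hanning(n_burst) * np.sin(2 * np.pi * p.theta_freq_hz *
                                         np.arange(n_burst) / fs)
    padded = np.concatenate([np.zeros(len(w)), burst, np.zeros(len(w))])
    g = float(np.max(np.abs(np.convolve(padded, w, mode="same")) ** 2))
    return float(np.sqrt(p.burst_snr * p_bg / g)) if p.burst_snr > 0 else 0.0


def simulate_session(params: SimulationParams):
    """Generate one encoding/recognition session.

    Returns ``(recording, events, behavior, truth)`` where ``truth`` is a
    :class:`SessionTruth`.  The same seed reproduces the session byte for
    byte.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    fs = p.fs
    n = p.n_pairs

    # encoding timeline: 2000 ms stimulus + U(1250, 1750) ms ISI
    isi = rng.uniform(1250.0, 1750.0, size=n - 1) if n > 1 else np.array([])
    onsets = np.empty(n)
    onsets[0] = 3000.0  # pre-roll covers the buffered pre-stimulus context
    for i in range(1, n):
        onsets[i] = onsets[i - 1] + 2000.0 + isi[i - 1]
    rec_end_ms = onsets[-1] + 2500.0 + 2000.0
    n_samples = int(round(rec_end_ms * fs / 1000.0))

    labels = list(STANDARD_CHANNELS)
    data = _background(rng, labels, n_samples, p)

    # behavioral outcome decides which encoding trials carry a burst
    n_hits = int(round(p.hit_rate * n))
    successful = np.sort(rng.choice(n, size=n_hits, replace=False))
    succ_set = set(successful.tolist())

    amp = _burst_amplitude(rng, p) if p.burst_snr > 0 else 0.0
    n_burst = int(round(p.burst_duration_ms * fs / 1000.0))
    half_ms = p.burst_duration_ms / 2.0
    window = np.hanning(n_burst)
    cp_idx = [labels.index(c) for c in CENTROPARIETAL]
    centers: dict = {}
    for i in successful:
        center = p.burst_onset_ms + half_ms + rng.normal(0.0, p.burst_jitter_sd_ms)
        center = float(np.clip(center, 250.0 + half_ms, 1250.0 - half_ms))
        centers[f"enc{i:03d}"] = center
        start = int(round((onsets[i] + center - half_ms) * fs / 1000.0))
        phase = rng.uniform(0, 2 * np.pi)
        burst = amp * window * np.sin(
            2 * np.pi * p.theta_freq_hz * np.arange(n_burst) / fs + phase)
        data[cp_idx, start:start + n_burst] += burst

    recording = Recording(data, fs, labels, {"synthetic": True, "seed": p.seed})

    # event table: encoding block, then recognition beyond the recorded span
    enc_rows = [{"onset_ms": float(onsets[i]), "block": "encoding",
                 "trial_id": f"enc{i:03d}", "pair_id": f"P{i:03d}"} for i in range(n)]
    rec_onset = rec_end_ms + 5000.0
    order = rng.permutation(2 * n)
    # first n slots are intact (old) probes of pair i, last n are recombined
    shift = rng.integers(1, n) if n > 1 else 0
    probes = [("old", f"P{i:03d}") for i in range(n)] + \
             [("recombined", f"P{i:03d}+P{(i + shift) % n:03d}") for i in range(n)]
    rec_rows, beh_rows = [], []
    n_cr = int(round(p.cr_rate * n))
    cr_correct = set(rng.choice(n, size=n_cr, replace=False).tolist())
    k_rec = 0
    t_cursor = rec_onset
    for slot in order:
        truth, pair = probes[slot]
        tid = f"rec{k_rec:03d}"
        rec_rows.append({"onset_ms": float(t_cursor), "block": "recognition",
                         "trial_id": tid, "pair_id": pair})
        if truth == "old":
            i = int(pair[1:])
            response = "old" if i in succ_set else "recombined"
        else:
            i = slot - n
            response = "recombined" if i in cr_correct else "old"
        beh_rows.append({"trial_id": tid, "truth": truth, "response": response})
        t_cursor += 2500.0 + rng.uniform(500.0, 1000.0)
        k_rec += 1

    events = pd.DataFrame(enc_rows + rec_rows)
    behavior = pd.DataFrame(beh_rows)
    truth = SessionTruth(p.theta_freq_hz, [f"enc{i:03d}" for i in successful],
                         centers, asdict(p))
    return recording, events, behavior, truth


def simulate_resting(params: SimulationParams, duration_s: float = 180.0) -> Recording:
    """Eyes-open resting-state surrogate: 1/f noise plus posterior alpha.

    Stationary by construction — no event-locked theta — so the downstream
    theta share stays near (or below) what chance peak-picking produces.
    """
    if duration_s < 3.5:
        raise ValueError("resting recording must cover at least one 3.5 s epoch")
    p = params
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 0x5E57]))
    n_samples = int(round(duration_s * p.fs))
    labels = list(STANDARD_CHANNELS)
    data = _background(rng, labels, n_samples, p)
    return Recording(data, p.fs, labels, {"synthetic": True, "resting": True,
                                          "seed": p.seed})
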