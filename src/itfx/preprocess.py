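"""Continuous-signal conditioning and automated epoch rejection.

The conditioning chain is: high-pass at 0.1 Hz, power-line removal at 50 Hz,
epoching, then amplitude-based epoch rejection.  Manual inspection of channels
and epochs is replaced by a peak-to-peak criterion (default 150 µV) plus an
explicit excluded-channel list, because reproducibility requires an automated
rule.  Eye-artifact removal by ICA is out of scope; real recordings should be
pre-cleaned before entering this pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import LABEL_REJECTED, EpochSet, Recording

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    highpass_hz: float = 0.1
    line_freq_hz: float = 50.0
    reject_ptp_uv: float = 150.0
    excluded_channels: list[str] = field(default_factory=list)
    line_method: str = "notch"  # "notch" | "spectrum_fit"

    def __post_init__(self) -> None:
        if self.highpass_hz <= 0:
            raise ValueError("highpass_hz must be positive")
        if self.line_freq_hz not in (50.0, 60.0):
            raise ValueError("line_freq_hz must be 50 or 60")
        if self.reject_ptp_uv <= 0:
            raise ValueError("reject_ptp_uv must be positive")


def highpass(recording: Recording, cutoff_hz: float = 0.1) -> Recording:
    """Zero-phase Butterworth high-pass (order 4, forward-backward).

    Attenuates DC by far more than 40 dB while leaving oscillatory content
    above ~1 Hz essentially untouched.
    """
    if cutoff_hz >= recording.fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist ({recording.fs / 2} Hz)")
    sos = signal.butter(4, cutoff_hz, btype="highpass", fs=recording.fs, output="sos")
    out = signal.sosfiltfilt(sos, recording.data, axis=-1)
    meta = dict(recording.meta)
    meta["filters"] = list(meta.get("filters", [])) + [
        {"type": "highpass", "cutoff_hz": cutoff_hz}]
    return Recording(out, recording.fs, list(recording.channel_labels), meta)


def remove_line_noise(recording: Recording, line_freq_hz: float = 50.0,
                      method: str = "notch", notch_q: float = 50.0) -> Recording:
    """Suppress power-line interference.

    method="notch" (default) applies a zero-phase IIR notch whose -3 dB width
    is ``line_freq_hz / notch_q`` (1 Hz by default), leaving bands more than
    2 Hz away essentially unchanged.  method="spectrum_fit" delegates to the
    multitaper regression approach (CleanLine-style) as implemented in MNE.
    """
    if line_freq_hz >= recording.fs / 2:
        raise ValueError("line frequency must be below Nyquist")
    if method == "notch":
        b, a = signal.iirnotch(line_freq_hz, Q=notch_q, fs=recording.fs)
        out = signal.filtfilt(b, a, recording.data, axis=-1)
    elif method == "spectrum_fit":
        import mne

        out = mne.filter.notch_filter(
            recording.data, Fs=recording.fs, freqs=line_freq_hz,
            method="spectrum_fit", verbose="error")
    else:
        raise ValueError(f"unknown line-noise method {method!r}")
    meta = dict(recording.meta)
    meta["filters"] = list(meta.get("filters", [])) + [
        {"type": "line_noise", "freq_hz": line_freq_hz, "method": method}]
    return Recording(out, recording.fs, list(recording.channel_labels), meta)


def reject_epochs(epochs: EpochSet, reject_ptp_uv: float = 150.0,
                  excluded_channels: list[str] | None = None,
                  within_ms: tuple[float, float] | None = None) -> EpochSet:
    """Label trials whose any-channel peak-to-peak amplitude exceeds a threshold.

    Retained data is never altered, only labels change.  Channels in
    ``excluded_channels`` do not contribute to the criterion; ``within_ms``
    restricts the criterion to a time range (so context cut around the epoch
    for decomposition purposes does not drive rejection).
    """
    if reject_ptp_uv <= 0:
        raise ValueError("reject_ptp_uv must be positive")
    excluded = set(excluded_channels or ())
    ch_mask = np.array([c not in excluded for c in epochs.channel_labels])
    data = epochs.data
    if within_ms is not None:
        t = epochs.times_ms
        data = data[..., (t >= within_ms[0]) & (t < within_ms[1])]
    ptp = np.ptp(data[:, ch_mask, :], axis=-1).max(axis=-1)
    labels = epochs.labels.copy()
    n_new = 0
    for i in range(epochs.n_trials):
        if labels[i] != LABEL_REJECTED and ptp[i] > reject_ptp_uv:
            labels[i] = LABEL_REJECTED
            n_new += 1
            logger.info("trial %r rejected: ptp %.1f uV > %.1f uV",
                        epochs.trial_ids[i], ptp[i], reject_ptp_uv)
    if np.all(labels == LABEL_REJECTED):
        raise ValueError(
            "all trials rejected; review the peak-to-peak threshold "
            f"({reject_ptp_uv} uV) against the data's amplitude range")
    logger.info("rejected %d/%d trials at %.1f uV peak-to-peak",
                n_new, epochs.n_trials, reject_ptp_uv)
    return EpochSet(epochs.data, epochs.fs, list(epochs.channel_labels), epochs.t0_ms,
                    epochs.t1_ms, epochs.baseline_ms, labels, list(epochs.trial_ids))


def preprocess_recording(recording: Recording, config: PreprocessConfig) -> Recording:
    """High-pass then line-noise removal, in the pipeline's fixed order."""
    rec = highpass(recording, config.highpass_hz)
    rec = remove_line_noise(rec, config.line_freq_hz, method=config.line_method)
    return rec
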