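"""Reading recordings, events and behavior; epoching; subsequent-memory labeling.

Conventions
-----------
* All signal amplitudes are in microvolts (µV); time is in milliseconds
  relative to stimulus onset unless a variable is suffixed otherwise.
* Intervals are half-open ``[a, b)`` when converted to samples; the onset
  sample belongs to the post-stimulus side.
* Millisecond→sample mapping uses round-half-away-from-zero so epoch shapes
  are bit-reproducible across platforms.

Event tables are TSV with columns ``onset_ms, block, trial_id, pair_id``
(``block`` is ``encoding`` or ``recognition``); behavior tables are TSV with
columns ``trial_id, truth, response`` where truth/response are ``old`` or
``recombined`` (an empty response marks an omission).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: channel montage used by the recording system (10-10 names)
STANDARD_CHANNELS = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8", "T7", "T8", "Cz",
    "C3", "C4", "CP5", "CP6", "Pz", "P3", "P4", "PO7", "PO8", "Oz",
)

EVENT_COLUMNS = ("onset_ms", "block", "trial_id", "pair_id")
BEHAVIOR_COLUMNS = ("trial_id", "truth", "response")

LABEL_SUCCESSFUL = "successful"
LABEL_UNSUCCESSFUL = "unsuccessful"
LABEL_UNLABELED = "unlabeled"
LABEL_REJECTED = "rejected"
EPOCH_LABELS = (LABEL_SUCCESSFUL, LABEL_UNSUCCESSFUL, LABEL_UNLABELED, LABEL_REJECTED)


def ms_to_samples(t_ms, fs: float):
    """Convert milliseconds to sample counts, rounding half away from zero."""
    x = np.asarray(t_ms, dtype=float) * fs / 1000.0
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out.astype(np.int64) if out.ndim else int(out)


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        10-10 channel names; must be unique.
    meta : dict
        Free-form provenance (source path, filter history, ...).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; available: {self.channel_labels}"
            ) from None

    def pick(self, labels) -> "Recording":
        idx = [self.channel_index(l) for l in labels]
        return Recording(self.data[idx].copy(), self.fs, [self.channel_labels[i] for i in idx],
                         dict(self.meta))


@dataclass
class EpochSet:
    """Trials cut around stimulus onsets, baseline-corrected in the time domain.

    ``data`` has shape (n_trials, n_channels, n_samples); the epoch clock runs
    from ``t0_ms`` to ``t1_ms`` with the onset at 0 ms.  ``labels`` holds one of
    ``successful | unsuccessful | unlabeled | rejected`` per trial.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    t0_ms: float = -1000.0
    t1_ms: float = 2500.0
    baseline_ms: tuple[float, float] = (-800.0, 0.0)
    labels: np.ndarray = None
    trial_ids: list = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        n = self.data.shape[0]
        if self.labels is None:
            self.labels = np.array([LABEL_UNLABELED] * n, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
            bad = set(self.labels) - set(EPOCH_LABELS)
            if bad:
                raise ValueError(f"unknown epoch labels: {sorted(bad)}")
        if self.trial_ids is None:
            self.trial_ids = list(range(n))
        expected = int(round((self.t1_ms - self.t0_ms) * self.fs / 1000.0))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"sample count {self.data.shape[2]} != round((t1-t0)*fs/1000) = {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times on the epoch clock (onset = 0 ms)."""
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs

    def select(self, labels) -> "EpochSet":
        """Subset trials whose label is in ``labels``."""
        labels = {labels} if isinstance(labels, str) else set(labels)
        mask = np.array([l in labels for l in self.labels])
        return EpochSet(self.data[mask], self.fs, self.channel_labels, self.t0_ms,
                        self.t1_ms, self.baseline_ms, self.labels[mask],
                        [t for t, m in zip(self.trial_ids, mask) if m])

    def label_counts(self) -> dict[str, int]:
        return {l: int(np.sum(self.labels == l)) for l in EPOCH_LABELS}


# ---------------------------------------------------------------------------
# recordings


def read_recording(path, format: str = "edf") -> Recording:
    """Read a continuous recording from EDF or from the HDF5 fixture container.

    Channel labels that match the 10-10 montage case-insensitively are mapped
    to canonical spelling; unknown labels are preserved verbatim with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne returns volts
        labels = list(raw.ch_names)
        fs = float(raw.info["sfreq"])
    elif format == "fixture":
        rec, _, _ = read_fixture(path)
        data, labels, fs = rec.data, rec.channel_labels, rec.fs
    else:
        raise ValueError(f"format must be 'edf' or 'fixture', got {format!r}")
    if data.shape[0] == 0:
        raise ValueError(f"{path}: recording contains zero channels")
    canonical = {c.lower(): c for c in STANDARD_CHANNELS}
    mapped = []
    for lab in labels:
        if lab.lower() in canonical:
            mapped.append(canonical[lab.lower()])
        else:
            logger.warning("unrecognized channel label %r kept verbatim", lab)
            mapped.append(lab)
    return Recording(data, fs, mapped, {"source": str(path), "format": format})


def write_fixture(path, recording: Recording, events: pd.DataFrame | None = None,
                  behavior: pd.DataFrame | None = None) -> None:
    """Write a single-file HDF5 container with the signal and optional tables.

    The container exists so tests and simulations need no EDF writer; EDF
    remains the interchange format for real recordings.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.attrs["fs"] = recording.fs
        f.attrs["channel_labels"] = [c.encode() for c in recording.channel_labels]
        f.attrs["meta"] = json.dumps(recording.meta, sort_keys=True, default=str)
        if events is not None:
            f.create_dataset("events_tsv", data=events.to_csv(sep="\t", index=False))
        if behavior is not None:
            f.create_dataset("behavior_tsv", data=behavior.to_csv(sep="\t", index=False))


def read_fixture(path):
    """Read the HDF5 fixture container; returns (Recording, events, behavior)."""
    import io as _io

    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        labels = [c.decode() if isinstance(c, bytes) else str(c)
                  for c in f.attrs["channel_labels"]]
        meta = json.loads(f.attrs.get("meta", "{}"))
        events = behavior = None
        if "events_tsv" in f:
            events = pd.read_csv(_io.StringIO(f["events_tsv"][()].decode()), sep="\t")
        if "behavior_tsv" in f:
            behavior = pd.read_csv(_io.StringIO(f["behavior_tsv"][()].decode()), sep="\t")
    return Recording(data, fs, labels, meta), events, behavior


# ---------------------------------------------------------------------------
# tables


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_events(df)
    return df


def read_behavior(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_behavior(df)
    return df


def validate_events(events: pd.DataFrame) -> None:
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    for block, grp in events.groupby("block"):
        onsets = grp["onset_ms"].to_numpy(float)
        if not np.all(np.diff(onsets) > 0):
            raise ValueError(f"onsets not strictly increasing within block {block!r}")


def validate_behavior(behavior: pd.DataFrame) -> None:
    missing = set(BEHAVIOR_COLUMNS) - set(behavior.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    if behavior["trial_id"].duplicated().any():
        raise ValueError("behavior table has duplicate trial_id rows")
    ok = {"old", "recombined"}
    truths = set(behavior["truth"].astype(str))
    if not truths <= ok:
        raise ValueError(f"unknown truth values: {sorted(truths - ok)}")


def label_epochs(events: pd.DataFrame, behavior: pd.DataFrame) -> dict:
    """Subsequent-memory labels for encoding trials.

    An encoding trial is *successful* when its intact (old) pair was later
    judged "old" in the recognition block, *unsuccessful* when it was judged
    "recombined", and *unlabeled* when no old recognition trial references its
    pair (or the response is missing).  Recombined recognition trials carry no
    encoding label: only intact pairs map one-to-one onto encoding trials.

    Returns a dict ``encoding trial_id -> label``.
    """
    validate_events(events)
    validate_behavior(behavior)
    enc = events[events["block"] == "encoding"]
    rec = events[events["block"] == "recognition"]
    pair_to_enc: dict = {}
    for _, row in enc.iterrows():
        if row["pair_id"] in pair_to_enc:
            raise ValueError(f"duplicate encoding pair_id {row['pair_id']!r}")
        pair_to_enc[row["pair_id"]] = row["trial_id"]

    resp = behavior.set_index("trial_id")
    labels = {tid: LABEL_UNLABELED for tid in enc["trial_id"]}
    seen_pairs = set()
    for _, row in rec.iterrows():
        tid = row["trial_id"]
        if tid not in resp.index:
            continue
        if resp.loc[tid, "truth"] != "old":
            continue  # recombined probes do not map onto a single encoding trial
        pair = row["pair_id"]
        if pair not in pair_to_enc:
            raise ValueError(f"old recognition trial {tid!r} references unknown pair {pair!r}")
        if pair in seen_pairs:
            raise ValueError(f"pair {pair!r} referenced by more than one old recognition trial")
        seen_pairs.add(pair)
        response = resp.loc[tid, "response"]
        if pd.isna(response) or response == "":
            continue  # omitted response: leave unlabeled
        labels[pair_to_enc[pair]] = (
            LABEL_SUCCESSFUL if response == "old" else LABEL_UNSUCCESSFUL
        )
    return labels


def summarize_behavior(behavior: pd.DataFrame) -> dict:
    """Recognition performance: overall, hit and correct-rejection percentages."""
    validate_behavior(behavior)
    if len(behavior) == 0:
        raise ValueError("behavior table is empty")
    truth = behavior["truth"].astype(str)
    correct = (truth == behavior["response"].astype(str))
    old = truth == "old"
    out = {
        "n_trials": int(len(behavior)),
        "n_old": int(old.sum()),
        "n_recombined": int((~old).sum()),
        "overall_pct": 100.0 * correct.mean(),
        "hits_pct": 100.0 * correct[old].mean() if old.any() else float("nan"),
        "correct_rejections_pct": 100.0 * correct[~old].mean() if (~old).any() else float("nan"),
    }
    return out


# ---------------------------------------------------------------------------
# epoching


def _baseline_correct(data: np.ndarray, fs: float, t0_ms: float,
                      baseline_ms: tuple[float, float]) -> np.ndarray:
    b0 = ms_to_samples(baseline_ms[0] - t0_ms, fs)
    b1 = ms_to_samples(baseline_ms[1] - t0_ms, fs)
    base = data[..., b0:b1].mean(axis=-1, keepdims=True)
    return data - base


def epoch(recording: Recording, events: pd.DataFrame, t0_ms: float = -1000.0,
          t1_ms: float = 2500.0, baseline_ms: tuple[float, float] = (-800.0, 0.0),
          labels: dict | None = None, buffer_ms: float = 0.0) -> EpochSet:
    """Cut epochs around the encoding onsets of ``events``.

    Each epoch's per-channel mean over ``baseline_ms`` is subtracted (DC
    correction).  Trials that do not fit inside the recording are kept in the
    set with label ``rejected`` and zeroed data, so trial indexing stays
    aligned with the event table.

    ``buffer_ms`` widens the cut on both sides with real signal context, so a
    later wavelet decomposition sees no padded edge anywhere inside
    ``[t0_ms, t1_ms]`` (padding an epoch with a reflected copy of itself is
    coherent with strongly autocorrelated EEG background and would bias power
    near the edges).  The returned epoch clock runs from ``t0_ms - buffer_ms``
    to ``t1_ms + buffer_ms``.
    """
    validate_events(events)
    enc = events[events["block"] == "encoding"]
    fs = recording.fs
    t0_ms = t0_ms - buffer_ms
    t1_ms = t1_ms + buffer_ms
    n_samp = int(round((t1_ms - t0_ms) * fs / 1000.0))
    rel0 = ms_to_samples(t0_ms, fs)
    n_trials = len(enc)
    data = np.zeros((n_trials, recording.n_channels, n_samp))
    trial_labels = np.array([LABEL_UNLABELED] * n_trials, dtype=object)
    trial_ids = list(enc["trial_id"])
    for i, (_, row) in enumerate(enc.iterrows()):
        onset = ms_to_samples(row["onset_ms"], fs)
        start = onset + rel0
        if start < 0 or start + n_samp > recording.n_samples:
            trial_labels[i] = LABEL_REJECTED
            logger.info("trial %r rejected: epoch [%d, %d) outside recording",
                        row["trial_id"], start, start + n_samp)
            continue
        data[i] = recording.data[:, start:start + n_samp]
        if labels is not None:
            trial_labels[i] = labels.get(row["trial_id"], LABEL_UNLABELED)
    keep = trial_labels != LABEL_REJECTED
    data[keep] = _baseline_correct(data[keep], fs, t0_ms, baseline_ms)
    return EpochSet(data, fs, list(recording.channel_labels), t0_ms, t1_ms,
                    baseline_ms, trial_labels, trial_ids)


def segment_resting(recording: Recording, epoch_ms: float = 3500.0,
                    baseline_ms_first: float = 1000.0) -> EpochSet:
    """Segment resting-state EEG into consecutive non-overlapping epochs.

    Each epoch spans ``epoch_ms`` with a pseudo-onset placed at the end of the
    first ``baseline_ms_first`` ms, so the downstream analysis windows
    (250-1250 ms post-onset) apply unchanged.  The trailing remainder is
    discarded.
    """
    fs = recording.fs
    n_per = int(round(epoch_ms * fs / 1000.0))
    n_ep = recording.n_samples // n_per
    if n_ep < 1:
        raise ValueError(
            f"recording ({recording.duration_ms:.0f} ms) shorter than one "
            f"{epoch_ms:.0f} ms epoch")
    t0 = -baseline_ms_first
    t1 = epoch_ms - baseline_ms_first
    data = recording.data[:, :n_ep * n_per].reshape(recording.n_channels, n_ep, n_per)
    data = np.ascontiguousarray(np.moveaxis(data, 1, 0))
    baseline = (t0 + (baseline_ms_first - 800.0), 0.0)  # last 800 ms of the baseline segment
    data = _baseline_correct(data, fs, t0, baseline)
    labels = np.array([LABEL_UNLABELED] * n_ep, dtype=object)
    return EpochSet(data, fs, list(recording.channel_labels), t0, t1, baseline, labels)


def write_report(path, report: dict) -> None:
    """Write a run report as deterministic JSON (sorted keys, no timestamps)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
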