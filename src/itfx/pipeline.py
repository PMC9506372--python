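"""End-to-end runs: configuration, the extraction pipeline, and reports.

The pipeline order is fixed: high-pass filter, line-noise removal, epoching
with subsequent-memory labels, amplitude-based epoch rejection, Morlet
decomposition of the successful epochs, baseline-ratio ERSP, peak matrix,
modal-ITF extraction with the parieto-occipital fallback.  Reports are
deterministic JSON (same config + inputs + seed produce byte-identical
output) validated against a pydantic model; ``report_json_schema()`` emits
the corresponding JSON schema.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import __version__
from . import io as eio
from .itf import (BandScheme, DEFAULT_ELECTRODES, FALLBACK_ELECTRODES, WindowSpec,
                  compare_conditions, fallback_extract)
from .preprocess import PreprocessConfig, preprocess_recording, reject_epochs
from .tfr import ersp, morlet_power

logger = logging.getLogger(__name__)

#: below this many successful epochs the estimate is flagged as thin
MIN_RECOMMENDED_EPOCHS = 14

#: context cut around each epoch so that every analysis-band wavelet
#: (longest: 1.75 s at 2 Hz) sees real signal instead of a padded edge
DEFAULT_EPOCH_BUFFER_MS = 1800.0


class BandSharesModel(BaseModel):
    delta: float
    theta: float
    alpha: float
    other: float


class ITFReportModel(BaseModel):
    """Schema of the per-subject extraction report."""

    itf_hz: float | None
    reliability: float = Field(ge=0.0, le=1.0)
    reliability_class: str
    band_shares_pct: BandSharesModel
    tie: bool
    tie_candidates_hz: list[float]
    fallback_used: bool
    n_theta_cells: int
    n_cells: int
    n_epochs_used: int
    n_epochs_rejected: int
    epoch_label_counts: dict[str, int]
    warnings: list[str]
    config: dict
    package_version: str


class ControlReportModel(BaseModel):
    """Schema of the resting-state control report."""

    band_shares_pct: BandSharesModel
    n_epochs_used: int
    n_epochs_rejected: int
    am_theta_share_pct: float | None
    theta_share_difference_pct: float | None
    config: dict
    package_version: str


@dataclasses.dataclass
class RunConfig:
    """Full configuration of one extraction run; defaults are the study settings."""

    eeg_path: str | None = None
    eeg_format: str = "edf"
    events_path: str | None = None
    behavior_path: str | None = None
    rest_path: str | None = None
    output_dir: str = "."
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    window: WindowSpec = dataclasses.field(default_factory=WindowSpec)
    bands: BandScheme = dataclasses.field(default_factory=BandScheme)
    electrodes: tuple = DEFAULT_ELECTRODES
    fallback_electrodes: tuple = FALLBACK_ELECTRODES
    fallback_trigger_pct: float = 20.0
    per_trial_baseline: bool = False
    window_stat: str = "mean"
    epoch_buffer_ms: float = DEFAULT_EPOCH_BUFFER_MS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(raw)
        if "preprocess" in kw and isinstance(kw["preprocess"], dict):
            kw["preprocess"] = PreprocessConfig(**kw["preprocess"])
        if "window" in kw and isinstance(kw["window"], dict):
            kw["window"] = WindowSpec(**kw["window"])
        if "bands" in kw and isinstance(kw["bands"], dict):
            kw["bands"] = BandScheme(**{k: tuple(v) for k, v in kw["bands"].items()})
        for key in ("electrodes", "fallback_electrodes"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["electrodes"] = list(self.electrodes)
        d["fallback_electrodes"] = list(self.fallback_electrodes)
        return d


def report_json_schema() -> dict:
    """JSON schema the extraction reports validate against."""
    return ITFReportModel.model_json_schema()


def extract_session(recording: eio.Recording, events, behavior,
                    config: RunConfig | None = None):
    """Run the full ITF pipeline on in-memory objects.

    Returns ``(report_dict, peak_matrix)``.  The report is validated against
    :class:`ITFReportModel` before being returned.
    """
    cfg = config or RunConfig()
    warnings: list[str] = []

    rec = preprocess_recording(recording, cfg.preprocess)
    labels = eio.label_epochs(events, behavior)
    epochs = eio.epoch(rec, events, labels=labels,
                       buffer_ms=cfg.epoch_buffer_ms)
    epochs = reject_epochs(epochs, cfg.preprocess.reject_ptp_uv,
                           cfg.preprocess.excluded_channels,
                           within_ms=(-1000.0, 2500.0))
    counts = epochs.label_counts()
    successful = epochs.select(eio.LABEL_SUCCESSFUL)
    if successful.n_trials == 0:
        raise ValueError("no successful epochs survive labeling and rejection")
    if successful.n_trials < MIN_RECOMMENDED_EPOCHS:
        msg = (f"only {successful.n_trials} successful epochs "
               f"(< {MIN_RECOMMENDED_EPOCHS}); the ITF estimate may be unstable")
        warnings.append(msg)
        logger.warning(msg)

    needed = sorted(set(cfg.electrodes) |
                    (set(cfg.fallback_electrodes) & set(rec.channel_labels)))
    present = [c for c in needed if c in successful.channel_labels]
    missing_primary = [c for c in cfg.electrodes if c not in present]
    if missing_primary:
        raise KeyError(f"electrodes {missing_primary} absent from recording; "
                       f"available: {successful.channel_labels}")
    pad_mode = "zero" if cfg.epoch_buffer_ms >= 1000.0 else "reflect"
    tfr = morlet_power(successful, channels=present, pad=pad_mode)
    tfr = tfr.crop(-900.0, 1400.0)  # baseline + analysis windows
    ersp_map = ersp(tfr, per_trial=cfg.per_trial_baseline)
    result, matrix = fallback_extract(
        ersp_map, cfg.window, cfg.electrodes, cfg.fallback_electrodes,
        cfg.fallback_trigger_pct, cfg.bands, cfg.window_stat)

    report = result.to_dict()
    report.update({
        "n_epochs_used": successful.n_trials,
        "n_epochs_rejected": counts[eio.LABEL_REJECTED],
        "epoch_label_counts": counts,
        "warnings": warnings,
        "config": cfg.to_dict(),
        "package_version": __version__,
    })
    ITFReportModel.model_validate(report)
    return report, matrix


def control_session(rest_recording: eio.Recording, config: RunConfig | None = None,
                    am_report: dict | None = None):
    """Run the identical analysis on resting-state EEG (the control procedure).

    The recording is segmented into successive 3500 ms pseudo-epochs (first
    1000 ms as baseline) and pushed through the same ERSP / peak-matrix /
    band-share machinery.  When an AM report is supplied, the report includes
    the within-subject theta-share difference.
    """
    cfg = config or RunConfig()
    rec = preprocess_recording(rest_recording, cfg.preprocess)
    if rec.duration_ms < 3500.0:
        raise ValueError("resting recording shorter than one 3500 ms epoch")
    # pseudo-onsets 1000 ms into each consecutive 3500 ms segment, cut with
    # signal context like the task epochs; segments whose context does not
    # fit inside the recording are dropped by the bounds check
    import pandas as pd

    n_seg = int(rec.duration_ms // 3500.0)
    pseudo = pd.DataFrame([{"onset_ms": 1000.0 + 3500.0 * k, "block": "encoding",
                            "trial_id": f"rest{k:03d}", "pair_id": f"rest{k:03d}"}
                           for k in range(n_seg)])
    epochs = eio.epoch(rec, pseudo, buffer_ms=cfg.epoch_buffer_ms)
    epochs = reject_epochs(epochs, cfg.preprocess.reject_ptp_uv,
                           cfg.preprocess.excluded_channels,
                           within_ms=(-1000.0, 2500.0))
    kept = epochs.select([eio.LABEL_UNLABELED, eio.LABEL_SUCCESSFUL,
                          eio.LABEL_UNSUCCESSFUL])
    counts = epochs.label_counts()
    pad_mode = "zero" if cfg.epoch_buffer_ms >= 1000.0 else "reflect"
    tfr = morlet_power(kept, channels=[c for c in cfg.electrodes], pad=pad_mode)
    tfr = tfr.crop(-900.0, 1400.0)
    ersp_map = ersp(tfr, per_trial=cfg.per_trial_baseline)
    from .itf import band_shares, peak_matrix as _pm

    matrix = _pm(ersp_map, cfg.window, cfg.electrodes, stat=cfg.window_stat)
    shares = band_shares(matrix, cfg.bands)
    am_share = (am_report or {}).get("band_shares_pct", {}).get("theta")
    report = {
        "band_shares_pct": shares,
        "n_epochs_used": kept.n_trials,
        "n_epochs_rejected": counts[eio.LABEL_REJECTED],
        "am_theta_share_pct": am_share,
        "theta_share_difference_pct": (am_share - shares["theta"]
                                       if am_share is not None else None),
        "config": cfg.to_dict(),
        "package_version": __version__,
    }
    ControlReportModel.model_validate(report)
    return report, matrix


def run_extract(config: RunConfig) -> dict:
    """Path-based wrapper: read inputs, extract, write report/matrix/log files."""
    if not config.eeg_path or not config.events_path or not config.behavior_path:
        raise ValueError("eeg_path, events_path and behavior_path are required")
    recording = eio.read_recording(config.eeg_path, config.eeg_format)
    events = eio.read_events(config.events_path)
    behavior = eio.read_behavior(config.behavior_path)
    report, matrix = extract_session(recording, events, behavior, config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_report(out / "itf_report.json", report)
    matrix.to_frame().to_csv(out / "peak_matrix.tsv", sep="\t")
    return report

def run_control(config: RunConfig) -> dict:
    """Path-based wrapper for the resting-state control analysis."""
    if not config.rest_path:
        raise ValueError("rest_path is required for the control analysis")
    recording = eio.read_recording(config.rest_path, config.eeg_format)
    am_report = None
    am_path = Path(config.output_dir) / "itf_report.json"
    if am_path.exists():
        am_report = json.loads(am_path.read_text())
    report, matrix = control_session(recording, config, am_report)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_report(out / "control_report.json", report)
    matrix.to_frame().to_csv(out / "control_peak_matrix.tsv", sep="\t")
    return report


def compare_reports(am_reports: list[dict], control_reports: list[dict]):
    """Group-level paired comparison of AM vs resting theta shares.

    Takes per-subject report dicts (one AM and one control each, in matching
    order) and runs the paired signed-rank test on the theta shares.
    """
    am = [r["band_shares_pct"]["theta"] for r in am_reports]
    rs = [r["band_shares_pct"]["theta"] for r in control_reports]
    return compare_conditions(am, rs)
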