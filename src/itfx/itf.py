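"""Individual theta frequency: peak-frequency matrix, modal ITF, reliability.

The method scans the post-stimulus interval where associative-encoding theta
activity is expected (250-1250 ms) with 19 overlapping 100 ms windows stepped
by 50 ms, at six centroparietal electrodes (Cz, C3, C4, Pz, P3, P4).  Each of
the 114 (window, electrode) cells records the frequency with the highest ERSP
on the 0.5 Hz grid between 2 and 15 Hz.  The ITF is the modal frequency among
the cells whose peak falls in the theta band, and its *reliability* is the
fraction of those theta cells that carry the modal value — treating each cell
as a repeated measurement of the same underlying encoding rhythm.

Band conventions: delta [2, 4), theta [4, 8), alpha [8, 12] on the 0.5 Hz
grid, so the theta candidates are {4.0, 4.5, ..., 7.5}; 8.0 Hz counts as
alpha.  Cells above 12 Hz are tallied as "other".

When fewer than a configurable share of cells peak in theta, the electrode set
is extended with the parieto-occipital pair PO7/PO8 and the extraction is
repeated (fallback path for participants without prominent centroparietal
theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import stats

from .tfr import ERSPMap

DEFAULT_ELECTRODES = ("Cz", "C3", "C4", "Pz", "P3", "P4")
FALLBACK_ELECTRODES = ("PO7", "PO8")

RELIABILITY_CLASSES = ("singular", "highly_reliable", "reliable", "unreliable", "none")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout over the post-stimulus analysis interval (ms)."""

    start_ms: float = 250.0
    end_ms: float = 1250.0
    width_ms: float = 100.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if min(self.start_ms, self.end_ms, self.width_ms, self.step_ms) < 0:
            raise ValueError("window parameters must be non-negative")
        if self.step_ms <= 0:
            raise ValueError("step_ms must be positive")
        if self.width_ms > self.end_ms - self.start_ms:
            raise ValueError("width_ms exceeds the analysis interval")


@dataclass(frozen=True)
class BandScheme:
    """Half-open frequency bands on the analysis grid (Hz)."""

    delta: tuple[float, float] = (2.0, 4.0)   # [low, high)
    theta: tuple[float, float] = (4.0, 8.0)   # [low, high)
    alpha: tuple[float, float] = (8.0, 12.0)  # [low, high]

    def classify(self, f: float) -> str:
        if self.delta[0] <= f < self.delta[1]:
            return "delta"
        if self.theta[0] <= f < self.theta[1]:
            return "theta"
        if self.alpha[0] <= f <= self.alpha[1]:
            return "alpha"
        return "other"


@dataclass
class PeakMatrix:
    """Per-cell peak frequency and peak ERSP on a windows x electrodes grid."""

    peak_freq_hz: np.ndarray   # (n_windows, n_electrodes)
    peak_ersp: np.ndarray      # (n_windows, n_electrodes)
    windows_ms: list[tuple[float, float]]
    electrodes: list[str]

    @property
    def n_cells(self) -> int:
        return self.peak_freq_hz.size

    def to_frame(self):
        """Windows x electrodes table of peak frequencies (Hz) for TSV export."""
        import pandas as pd

        idx = [f"{int(a)}-{int(b)}ms" for a, b in self.windows_ms]
        return pd.DataFrame(self.peak_freq_hz, index=idx, columns=self.electrodes)


@dataclass
class ITFResult:
    """Modal theta frequency with reliability and band-occupancy context."""

    itf_hz: float                      # NaN when reliability_class == "none"
    reliability: float                 # share of theta cells carrying the ITF
    reliability_class: str
    band_shares: dict                  # % of cells peaking per band, sums to 100
    tie: bool = False
    tie_candidates: list[float] = field(default_factory=list)
    fallback_used: bool = False
    n_theta_cells: int = 0
    n_cells: int = 0

    def to_dict(self) -> dict:
        return {
            "itf_hz": None if np.isnan(self.itf_hz) else float(self.itf_hz),
            "reliability": float(self.reliability),
            "reliability_class": self.reliability_class,
            "band_shares_pct": {k: float(v) for k, v in self.band_shares.items()},
            "tie": bool(self.tie),
            "tie_candidates_hz": [float(c) for c in self.tie_candidates],
            "fallback_used": bool(self.fallback_used),
            "n_theta_cells": int(self.n_theta_cells),
            "n_cells": int(self.n_cells),
        }


def make_time_windows(spec: WindowSpec = WindowSpec()) -> list[tuple[float, float]]:
    """Enumerate half-open windows [s, s+width) while s+width <= end.

    Defaults give the 19 windows 250-350, 300-400, ..., 1150-1250 ms.
    """
    windows = []
    s = spec.start_ms
    while s + spec.width_ms <= spec.end_ms + 1e-9:
        windows.append((s, s + spec.width_ms))
        s += spec.step_ms
    return windows


def peak_matrix(ersp_map: ERSPMap, spec: WindowSpec = WindowSpec(),
                electrodes=DEFAULT_ELECTRODES, stat: str = "mean") -> PeakMatrix:
    """Peak frequency per (time window, electrode) cell.

    Within each window the ERSP is reduced over time samples per frequency
    (``stat="mean"`` by default — robust to single-sample noise; ``"max"``
    takes the single highest sample) and the frequency with the highest value
    wins.  Argmax ties break toward the lower frequency.
    """
    if stat not in ("mean", "max"):
        raise ValueError("stat must be 'mean' or 'max'")
    ch_idx = [ersp_map.channel_index(e) for e in electrodes]
    windows = make_time_windows(spec)
    t = ersp_map.times_ms
    n_w, n_e = len(windows), len(electrodes)
    peak_f = np.empty((n_w, n_e))
    peak_v = np.empty((n_w, n_e))
    for wi, (a, b) in enumerate(windows):
        tmask = (t >= a) & (t < b)
        if not tmask.any():
            raise ValueError(f"window [{a}, {b}) ms contains no time samples")
        block = ersp_map.ratio[ch_idx][:, :, tmask]  # (elec, freq, time)
        reduced = block.mean(axis=-1) if stat == "mean" else block.max(axis=-1)
        best = reduced.argmax(axis=-1)  # first occurrence = lowest frequency on ties
        peak_f[wi] = ersp_map.freqs_hz[best]
        peak_v[wi] = reduced[np.arange(n_e), best]
    return PeakMatrix(peak_f, peak_v, windows, list(electrodes))


def band_shares(matrix: PeakMatrix, bands: BandScheme = BandScheme()) -> dict:
    """Percentage of cells peaking in each band; shares sum to exactly 100.

    Computed with rational arithmetic on cell counts before the final float
    conversion, so the total carries no accumulation error.
    """
    if matrix.n_cells == 0:
        raise ValueError("empty peak matrix")
    counts = {"delta": 0, "theta": 0, "alpha": 0, "other": 0}
    for f in matrix.peak_freq_hz.ravel():
        counts[bands.classify(float(f))] += 1
    total = matrix.n_cells
    return {k: float(Fraction(100 * v, total)) for k, v in counts.items()}


def extract_itf(matrix: PeakMatrix, bands: BandScheme = BandScheme()) -> ITFResult:
    """Modal theta frequency of the peak matrix, with reliability.

    Reliability is (# cells equal to the ITF) / (# theta cells).  A multimodal
    count distribution sets ``tie=True`` and resolves toward the candidate with
    the larger summed ERSP over its cells (lower frequency on a further tie).
    With no theta cells at all the class is "none" and the ITF undefined.
    """
    if matrix.n_cells == 0:
        raise ValueError("empty peak matrix")
    freqs = matrix.peak_freq_hz.ravel()
    ersps = matrix.peak_ersp.ravel()
    shares = band_shares(matrix, bands)
    theta_mask = np.array([bands.classify(float(f)) == "theta" for f in freqs])
    n_theta = int(theta_mask.sum())
    if n_theta == 0:
        return ITFResult(float("nan"), 0.0, "none", shares,
                         n_theta_cells=0, n_cells=matrix.n_cells)
    theta_f = freqs[theta_mask]
    theta_e = ersps[theta_mask]
    cand, counts = np.unique(theta_f, return_counts=True)
    top = counts.max()
    winners = cand[counts == top]
    tie = len(winners) > 1
    if tie:
        mass = np.array([theta_e[theta_f == w].sum() for w in winners])
        # larger summed ERSP wins; np.argmax prefers the lower frequency on equality
        itf = float(winners[np.argmax(mass)])
    else:
        itf = float(winners[0])
    reliability = top / n_theta
    return ITFResult(itf, reliability, reliability_class(reliability), shares,
                     tie=tie, tie_candidates=[float(w) for w in winners] if tie else [],
                     n_theta_cells=n_theta, n_cells=matrix.n_cells)


def reliability_class(reliability: float) -> str:
    """Five-level reliability scale partitioning [0, 1].

    (0.80, 1] singular; (0.50, 0.80] highly_reliable; (0.30, 0.50] reliable;
    [0.15, 0.30] unreliable; [0, 0.15) none — below 1/8, the chance level for
    eight theta grid candidates.
    """
    if not 0.0 <= reliability <= 1.0:
        raise ValueError(f"reliability must lie in [0, 1], got {reliability}")
    if reliability > 0.80:
        return "singular"
    if reliability > 0.50:
        return "highly_reliable"
    if reliability > 0.30:
        return "reliable"
    if reliability >= 0.15:
        return "unreliable"
    return "none"


def fallback_extract(ersp_map: ERSPMap, spec: WindowSpec = WindowSpec(),
                     primary_electrodes=DEFAULT_ELECTRODES,
                     fallback_electrodes=FALLBACK_ELECTRODES,
                     trigger_theta_share_pct: float = 20.0,
                     bands: BandScheme = BandScheme(),
                     stat: str = "mean") -> tuple[ITFResult, PeakMatrix]:
    """Extraction with a parieto-occipital fallback for weak centroparietal theta.

    If the primary matrix's theta share falls below ``trigger_theta_share_pct``
    the matrix is rebuilt with ``fallback_electrodes`` appended and the ITF
    re-extracted (``fallback_used=True``).  Missing fallback electrodes degrade
    gracefully to the primary result with a warning.
    """
    import logging

    matrix = peak_matrix(ersp_map, spec, primary_electrodes, stat=stat)
    result = extract_itf(matrix, bands)
    if result.band_shares["theta"] >= trigger_theta_share_pct:
        return result, matrix
    missing = [e for e in fallback_electrodes if e not in ersp_map.channel_labels]
    if missing:
        logging.getLogger(__name__).warning(
            "fallback electrodes %s absent; returning primary result", missing)
        return result, matrix
    extended = list(primary_electrodes) + list(fallback_electrodes)
    matrix2 = peak_matrix(ersp_map, spec, extended, stat=stat)
    result2 = extract_itf(matrix2, bands)
    result2.fallback_used = True
    return result2, matrix2


@dataclass
class PairedComparison:
    statistic: float
    p_value: float
    direction: str      # "am_greater" | "rest_greater" | "none"
    n: int
    mean_difference: float


def compare_conditions(am_theta_shares, rs_theta_shares) -> PairedComparison:
    """Paired two-sided Wilcoxon signed-rank test on per-subject theta shares.

    Compares the share of matrix cells peaking in theta between the
    associative-memory task and resting state.  Requires at least five pairs;
    identical samples return p = 1 (no evidence of a difference).
    """
    am = np.asarray(am_theta_shares, float)
    rs = np.asarray(rs_theta_shares, float)
    if am.shape != rs.shape or am.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = len(am)
    if n < 5:
        raise ValueError(f"need at least 5 pairs for the signed-rank test, got {n}")
    d = am - rs
    if np.allclose(d, 0):
        return PairedComparison(0.0, 1.0, "none", n, 0.0)
    res = stats.wilcoxon(am, rs, zero_method="wilcox", alternative="two-sided")
    mean_d = float(d.mean())
    direction = "am_greater" if mean_d > 0 else ("rest_greater" if mean_d < 0 else "none")
    return PairedComparison(float(res.statistic), float(res.pvalue), direction, n, mean_d)
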