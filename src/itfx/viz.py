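"""Static QC figures: per-subject time-frequency map and peak-matrix heatmap."""

from __future__ import annotations

import numpy as np

from .itf import PeakMatrix
from .tfr import ERSPMap


def plot_ersp_map(ersp_map: ERSPMap, channel: str, ax=None, vmax: float | None = None):
    """Time-frequency ERSP image for one electrode (ratio scale, 1 = baseline)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ci = ersp_map.channel_index(channel)
    t, f = ersp_map.times_ms, ersp_map.freqs_hz
    im = ax.pcolormesh(t, f, ersp_map.ratio[ci], shading="nearest",
                       cmap="magma", vmin=0.0, vmax=vmax)
    ax.axvline(0.0, color="w", lw=0.8, ls="--")
    ax.set(xlabel="time (ms)", ylabel="frequency (Hz)",
           title=f"ERSP ratio, {channel}")
    ax.figure.colorbar(im, ax=ax, label="power / baseline")
    return ax


def plot_peak_matrix(matrix: PeakMatrix, ax=None, theta_band=(4.0, 8.0)):
    """Windows x electrodes heatmap of per-cell peak frequencies (Hz).

    Theta-band cells — the ones that vote for the ITF — are outlined.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 7))
    vals = matrix.peak_freq_hz
    im = ax.imshow(vals, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(matrix.electrodes)), matrix.electrodes)
    ax.set_yticks(range(len(matrix.windows_ms)),
                  [f"{int(a)}-{int(b)}" for a, b in matrix.windows_ms], fontsize=7)
    ax.set(xlabel="electrode", ylabel="window (ms)", title="peak frequency (Hz)")
    lo, hi = theta_band
    for (wi, ci), v in np.ndenumerate(vals):
        if lo <= v < hi:
            ax.add_patch(Rectangle((ci - 0.5, wi - 0.5), 1, 1, fill=False,
                                   edgecolor="w", lw=0.7))
    ax.figure.colorbar(im, ax=ax, label="Hz")
    return ax
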