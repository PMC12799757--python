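"""Plotting helpers: band-trajectory panels and deviation bar charts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import WINDOWS, CVReport
from .normalization import normalize
from .spectra import Recording

__all__ = ["plot_band_trajectories", "plot_window_deviations"]


def plot_band_trajectories(
    recordings: list[Recording],
    bands: tuple[int, ...] = (24, 165),
    method: str = "divide",
    path: str | Path | None = None,
):
    """Per-subject normalized intensity of selected bands over hematoma age.

    One panel per band (1-based index); each line is one subject. The
    classic pattern: the ~470 nm band dips mid-course (bilirubin), the
    ~885 nm band dips early (whole blood) and recovers toward skin.
    """
    dataset = normalize(recordings, method)
    fig, axes = plt.subplots(1, len(bands), figsize=(5 * len(bands), 4), squeeze=False)
    for ax, band in zip(axes[0], bands):
        for subject in np.unique(dataset.subject):
            m = dataset.subject == subject
            order = np.argsort(dataset.y[m])
            ax.plot(dataset.y[m][order] / 24.0, dataset.X[m, band - 1][order], alpha=0.5, lw=1)
        nm = dataset.grid.band_to_wavelength(band)
        ax.set_title(f"band {band} ({nm:.0f} nm), {method}")
        ax.set_xlabel("hematoma age [days]")
        ax.set_ylabel("normalized intensity")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_window_deviations(reports: dict[str, CVReport], path: str | Path | None = None):
    """Grouped bars of across-subject mean deviation (M) with SD whiskers.

    ``reports`` maps a model label to its CV report; bars are grouped by
    age window (up to day 7, after day 7, full period).
    """
    labels = list(reports)
    x = np.arange(len(WINDOWS))
    width = 0.8 / max(len(labels), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, label in enumerate(labels):
        stats = reports[label].window_stats
        means = [stats.get(w, (np.nan, None))[0] for w in WINDOWS]
        sds = [stats.get(w, (np.nan, None))[1] or 0.0 for w in WINDOWS]
        ax.bar(x + (i - (len(labels) - 1) / 2) * width, means, width, yerr=sds,
               capsize=3, label=label)
    ax.set_xticks(x, ["up to day 7", "after day 7", "full period"])
    ax.set_ylabel("mean absolute deviation [days]")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
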