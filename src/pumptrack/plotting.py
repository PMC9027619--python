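"""Convenience plots: detection audit traces and averaged power signatures."""

from __future__ import annotations

import numpy as np

from .expected_power import ExpectedPowerModel
from .io import SECONDS_PER_DAY, Snapshot
from .tracking import DetectionSeries


def plot_detection_series(series: DetectionSeries, ax=None):
    """Power-tracking audit plot: MAs, d1 integral and combined flags."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    f = series.frame
    ax.plot(f["timestamp"], f["ma_short"], lw=0.8, label="short-term MA")
    ax.plot(f["timestamp"], f["ma_long"], lw=1.2, label="long-term MA")
    flagged = f[f["combined"]]
    if not flagged.empty:
        ax.plot(
            flagged["timestamp"], flagged["ma_short"], ".", ms=3,
            color="crimson", label="alarm",
        )
    ax.set_ylabel("power (W)")
    ax.legend(loc="upper left", fontsize=8)
    ax2 = ax.twinx()
    ax2.plot(f["timestamp"], f["integral"], lw=0.8, color="gray", alpha=0.6)
    ax2.set_ylabel("d1 integral (W·h)", color="gray")
    return ax


def signature_average(
    snapshots: list[Snapshot], model: ExpectedPowerModel, bin_hours: float = 6.0
):
    """Average normalized power versus time-to-diagnosis across snapshots.

    Returns ``(bin_centres_days, mean_normalized_power)`` over the −14…+1 day
    window; the normalisation (power / expected power at set speed) makes
    patients at different set speeds comparable.
    """
    edges = np.arange(-14.0, 1.0 + 1e-9, bin_hours / 24.0)
    centres = 0.5 * (edges[:-1] + edges[1:])
    sums = np.zeros(len(centres))
    counts = np.zeros(len(centres))
    for snap in snapshots:
        rel = (
            (snap.timestamps - snap.event_time).dt.total_seconds().to_numpy()
            / SECONDS_PER_DAY
        )
        norm = snap.power / model.expected_power(snap.speed)
        idx = np.clip(np.digitize(rel, edges) - 1, 0, len(centres) - 1)
        np.add.at(sums, idx, norm)
        np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return centres, mean


def plot_signature_average(snapshots, model, ax=None, **kwargs):
    """Plot the averaged normalized power signature of a snapshot cohort."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    centres, mean = signature_average(snapshots, model, **kwargs)
    ax.plot(centres, mean, lw=1.2)
    ax.axvline(0.0, ls="--", color="k", lw=0.8)
    ax.set_xlabel("days from diagnosis")
    ax.set_ylabel("normalized power (–)")
    return ax
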