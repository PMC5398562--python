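"""Plot helpers: signal histograms and bivariate cell-cycle scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless
import matplotlib.pyplot as plt
import numpy as np

from .stats import CellCycleProfile, signal_histogram


def plot_signal_histogram(signals, n_bins: int = 50, ax=None, label=None):
    """Histogram of per-nucleus label signals (equal-width bins over [0, max])."""
    hist = signal_histogram(signals, n_bins)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    widths = hist["bin_right"] - hist["bin_left"]
    ax.bar(hist["bin_left"], hist["count"], width=widths, align="edge",
           alpha=0.7, label=label)
    ax.set_xlabel("mean nuclear signal (AU)")
    ax.set_ylabel("nuclei")
    if label:
        ax.legend()
    return ax


def plot_bivariate(dna, label_signal, profile: CellCycleProfile | None = None,
                   ax=None):
    """Replication signal vs DNA content with the cell-cycle gates drawn."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = np.asarray(dna, dtype=float)
    y = np.asarray(label_signal, dtype=float)
    ax.scatter(x, np.log1p(y), s=4, alpha=0.4, linewidths=0)
    ax.set_xlabel("DNA content (AU)")
    ax.set_ylabel("log1p replication signal")
    if profile is not None:
        ax.axhline(np.log1p(profile.label_threshold), color="crimson", lw=1,
                   label="label gate")
        if np.isfinite(profile.dna_g1_mode):
            cut = 0.5 * (profile.dna_g1_mode + profile.dna_g2_mode)
            ax.axvline(cut, color="darkorange", lw=1, label="G1/G2M gate")
        ax.set_title(
            f"G1 {profile.frac_g1:.2f} / S {profile.frac_s:.2f} / "
            f"G2M {profile.frac_g2m:.2f}"
        )
        ax.legend(loc="upper left", fontsize=8)
    return ax


def save_figure(ax, path) -> None:
    ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(ax.figure)


__all__ = ["plot_bivariate", "plot_signal_histogram", "save_figure"]
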