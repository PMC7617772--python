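"""Small plotting helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_dnds_bins(bins, path):
    """dN/dS as a function of inversion-correlation bin."""
    mids = [(b.lo + b.hi) / 2 for b in bins]
    vals = [b.dnds for b in bins]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.plot(mids, vals, "o-")
    ax.set_xlabel("inversion correlation coefficient (r)")
    ax.set_ylabel("normalised dN/dS")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_divergence_density(results, path, label=""):
    """Density-style histogram of pairwise divergence times."""
    ts = np.array([r.t for r in results])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(ts, bins=30, density=True, alpha=0.7)
    ax.set_xlabel("divergence time (generations)")
    ax.set_ylabel("density")
    if label:
        ax.set_title(label)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_pc1_track(window_regions, track, path, region=None):
    """Per-sample windowed PC1 along a chromosome."""
    mids = np.array([(r.start + r.end) / 2 for r in window_regions])
    fig, ax = plt.subplots(figsize=(8, 4))
    for j in range(track.shape[1]):
        ax.plot(mids, track[:, j], lw=0.7, alpha=0.6)
    if region is not None:
        ax.axvspan(region.start, region.end, color="orange", alpha=0.2)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("windowed PC1")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
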