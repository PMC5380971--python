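"""Quick-look plots for morphometry and dynamics outputs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_size_histogram(hist: pd.DataFrame, path: str | Path) -> Path:
    """Bar plot of the population droplet-area histogram (counts per bin)."""
    total = hist.loc["total"]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(range(len(total)), total.values, color="#4878b0")
    ax.set_xticks(range(len(total)), total.index, rotation=45, ha="right")
    ax.set_xlabel("area bin (μm²)")
    ax.set_ylabel("droplets")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_cluster_rates(cells: pd.DataFrame, path: str | Path) -> Path:
    """Mean ± s.e.m. of clusters per 100 droplets per cell, by cluster size."""
    cols = ["rate_2", "rate_3", "rate_4", "rate_5", "rate_6plus"]
    vals = cells[cols].apply(pd.to_numeric, errors="coerce")
    mean = vals.mean()
    sem = vals.sem()
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(range(len(cols)), mean.values, yerr=sem.values, capsize=3, color="#b04848")
    ax.set_xticks(range(len(cols)), ["2", "3", "4", "5", "≥6"])
    ax.set_xlabel("droplets per cluster")
    ax.set_ylabel("clusters / 100 LDs / cell")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_line_profile(positions_um: np.ndarray, values: np.ndarray, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(4, 2.5))
    ax.plot(positions_um, values, lw=1.2)
    ax.set_xlabel("position (μm)")
    ax.set_ylabel("intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
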