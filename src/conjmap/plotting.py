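"""Matplotlib figures: overlap curves with null bands, network bar charts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .conjunction import OverlapCurve
from .null_model import NullDistribution

SCENARIO_COLORS = {
    "EMB1": "#40E0D0",  # turquoise: shift-towards-maleness, increases
    "EMB2": "#1f4ea1",  # blue: shift-towards-maleness, decreases
    "GI1": "#ff8c00",  # orange: shift-towards-femaleness, increases
    "GI2": "#ffd700",  # yellow: shift-towards-femaleness, decreases
}


def plot_overlap_curves(
    curves: dict[str, OverlapCurve],
    null: NullDistribution,
    path,
    title: str = "",
) -> Path:
    """Overlap percentage vs. -log10(p) with median and 0.5/99.5 null bands."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    grid = next(iter(curves.values())).grid
    import numpy as np

    x = -np.log10(grid.p_values)
    ax.plot(x, null.band(50.0), "k-", lw=1.2, label="null median")
    ax.plot(x, null.band(99.5), "k:", lw=1.0, label="null 0.5 / 99.5 pct")
    ax.plot(x, null.band(0.5), "k:", lw=1.0)
    for name, curve in curves.items():
        ax.plot(
            x,
            curve.overlap_percent,
            color=SCENARIO_COLORS.get(name, "gray"),
            lw=1.8,
            label=name,
        )
    ax.set_xlabel(r"voxel-level threshold, $-\log_{10}(p)$")
    ax.set_ylabel("spatial overlap (%)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_network_bars(table: pd.DataFrame, path, title: str = "") -> Path:
    """Per-network percentage bar chart for one conjunction mask."""
    path = Path(path)
    plot_tab = table[table["name"] != "unassigned"]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(plot_tab["name"], plot_tab["percent"], color="#4472c4")
    ax.set_ylabel("% of conjunction voxels")
    ax.tick_params(axis="x", rotation=45)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
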