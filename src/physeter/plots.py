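"""Minimal plotting helpers for pipeline reports (aesthetics are not a
contract)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_icigram", "plot_length_violins", "plot_overlap_bars", "plot_partial_fit"]

CLASS_COLORS = {"SG": "tab:green", "MS": "tab:orange", "AM": "tab:blue", "UNC": "0.6"}


def plot_icigram(bins, cell_ms: float = 10.0, max_ici_ms: float = 2000.0):
    """Concatenated per-bin ICI histograms as a time-by-ICI heat map."""
    mat = np.column_stack([b.ici_hist for b in bins]) if bins else np.zeros((200, 1))
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(
        mat, aspect="auto", origin="lower", cmap="viridis",
        extent=[0, max(len(bins), 1), 0, max_ici_ms],
    )
    ax.set_xlabel("5-min bin")
    ax.set_ylabel("ICI (ms)")
    return fig


def plot_length_violins(lengths_m, labels):
    df = pd.DataFrame({"length_m": lengths_m, "label": [str(l) for l in labels]})
    order = [c for c in ("SG", "MS", "AM") if (df["label"] == c).any()]
    fig, ax = plt.subplots(figsize=(5, 4))
    if order:
        data = [df.loc[df["label"] == c, "length_m"].to_numpy() for c in order]
        parts = ax.violinplot(data, showmedians=True)
        for body, c in zip(parts["bodies"], order):
            body.set_facecolor(CLASS_COLORS[c])
        ax.set_xticks(range(1, len(order) + 1), order)
    ax.set_ylabel("estimated length (m)")
    return fig


def plot_overlap_bars(ratios: dict):
    regions = ["SG", "MS", "AM", "SG+MS", "SG+AM", "MS+AM", "SG+MS+AM"]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    vals = [ratios.get(r, 0.0) for r in regions]
    ax.bar(regions, vals, color=[CLASS_COLORS.get(r, "0.4") for r in regions])
    ax.set_ylabel("fraction of presence units")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    return fig


def plot_partial_fit(pf: pd.DataFrame, color="0.2"):
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(pf["x"], pf["fit"], color=color)
    ax.fill_between(pf["x"], pf["lo"], pf["hi"], color=color, alpha=0.25)
    ax.set_xlabel("Julian day")
    ax.set_ylabel("P(presence)")
    return fig
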