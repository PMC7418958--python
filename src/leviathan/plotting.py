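"""Basic diagnostic plots for sweep results (matplotlib, no styling)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_group_summary(summary: pd.DataFrame, value: str = "mean_reputation"):
    """Group aggregate vs sigma_small, one line per (group, relation/design)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for (group, relation), sub in summary.groupby(["group", "relation"]):
        cell = sub.groupby("sigma_small")[value].mean()
        ax.plot(cell.index, cell.values, marker="o", label=f"{group} ({relation})")
    ax.set_xscale("log")
    ax.set_xlabel(r"$\sigma_S$")
    ax.set_ylabel(value.replace("_", " "))
    ax.legend()
    fig.tight_layout()
    return fig


def plot_occupancy(occupancy: pd.DataFrame):
    """Per-rank probability of occupancy by each group."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in occupancy.groupby("group"):
        cell = sub.groupby("rank")["probability"].mean()
        ax.plot(cell.index, cell.values, marker=".", label=f"group {group}")
    ax.set_xlabel("social rank (1 = best)")
    ax.set_ylabel("occupancy probability")
    ax.axhline(0.5, color="grey", lw=0.5)
    ax.legend()
    fig.tight_layout()
    return fig


def plot_advancement(advancement: pd.DataFrame):
    """P(non-worsening rank at next measurement) by group and current rank."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in advancement.groupby("group"):
        cell = sub.groupby("rank")["probability"].mean()
        ax.plot(cell.index, cell.values, marker=".", label=f"group {group}")
    ax.set_xlabel("current rank (1 = best)")
    ax.set_ylabel("P(rank improves or holds)")
    ax.legend()
    fig.tight_layout()
    return fig
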