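"""Publication-style figures: mean +/- SEM traces, heatmaps, violins.

All functions take tidy DataFrames produced by the analysis modules and save
straight to file with the non-interactive Agg backend.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .protocol import StimulusProtocol

__all__ = [
    "plot_mean_sem_traces",
    "plot_heatmap",
    "plot_peaks_violin",
    "plot_speed_traces",
    "plot_behavior_violins",
]


def _shade_pulse(ax, protocol: StimulusProtocol) -> None:
    ax.axvspan(protocol.pulse_onset_s, protocol.pulse_offset_s, color="0.85", zorder=0)


def plot_mean_sem_traces(
    summaries: dict[str, pd.DataFrame], protocol: StimulusProtocol, path: str | Path
) -> None:
    """Group mean %dR/R0 traces with SEM shading and the pulse marked."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    _shade_pulse(ax, protocol)
    for group, df in summaries.items():
        ax.plot(df["t_s"], df["mean_pct"], label=group)
        ax.fill_between(
            df["t_s"], df["mean_pct"] - df["sem_pct"], df["mean_pct"] + df["sem_pct"], alpha=0.3
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("% ΔR/R₀")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(
    dr_matrix: np.ndarray, order: np.ndarray, t_s: np.ndarray,
    protocol: StimulusProtocol, path: str | Path, title: str = "",
) -> None:
    """Per-animal response heatmap, rows ordered by hierarchical clustering."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    vmax = max(1.0, float(np.percentile(np.abs(dr_matrix), 99)))
    im = ax.imshow(
        dr_matrix[order],
        aspect="auto",
        extent=(t_s[0], t_s[-1], dr_matrix.shape[0], 0),
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
    )
    for edge in (protocol.pulse_onset_s, protocol.pulse_offset_s):
        ax.axvline(edge, color="k", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("animal")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="% ΔR/R₀")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _violin(ax, groups: dict[str, np.ndarray], ylabel: str) -> None:
    labels = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    ax.violinplot(data, showmedians=True)
    for i, vals in enumerate(data, start=1):
        jitter = (np.arange(len(vals)) / max(1, len(vals) - 1) - 0.5) * 0.2
        ax.plot(np.full(len(vals), i) + jitter, vals, "k.", ms=3, alpha=0.6)
    ax.set_xticks(range(1, len(labels) + 1), labels, rotation=20)
    ax.set_ylabel(ylabel)


def plot_peaks_violin(calls_df: pd.DataFrame, path: str | Path, column: str = "max_pct") -> None:
    """Violin of per-animal peak amplitudes by group."""
    fig, ax = plt.subplots(figsize=(4, 3.5))
    groups = {g: grp[column].to_numpy() for g, grp in calls_df.groupby("group")}
    _violin(ax, groups, f"{column} (% ΔR/R₀)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_speed_traces(
    speed_summary: pd.DataFrame, protocol: StimulusProtocol, path: str | Path
) -> None:
    """Mean instantaneous speed per (group, gas) with SEM shading."""
    groups = sorted(speed_summary["group"].unique())
    fig, axes = plt.subplots(1, len(groups), figsize=(5 * len(groups), 3), squeeze=False)
    for ax, group in zip(axes[0], groups):
        _shade_pulse(ax, protocol)
        sub = speed_summary[speed_summary["group"] == group]
        for gas, color in (("air", "k"), ("CO2", "tab:blue")):
            g = sub[sub["gas"] == gas]
            if g.empty:
                continue
            ax.plot(g["t_s"], g["mean_mm_s"], color=color, label=gas)
            ax.fill_between(
                g["t_s"], g["mean_mm_s"] - g["sem_mm_s"], g["mean_mm_s"] + g["sem_mm_s"],
                color=color, alpha=0.3,
            )
        ax.set_title(group)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("speed (mm/s)")
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_behavior_violins(metrics: pd.DataFrame, path: str | Path) -> None:
    """Per-animal windowed speeds and state time ratios by group x gas."""
    cols = ["speed_early", "speed_late", "forward_ratio", "reverse_ratio", "pause_ratio"]
    fig, axes = plt.subplots(1, len(cols), figsize=(3.2 * len(cols), 3.2))
    for ax, col in zip(axes, cols):
        groups = {
            f"{g}\n{gas}": grp[col].to_numpy()
            for (g, gas), grp in metrics.groupby(["group", "gas"])
        }
        _violin(ax, groups, col)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
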