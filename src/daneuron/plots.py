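"""Figure export: voltage traces, frequency heatmaps, phase planes.

Figures are presentation artifacts only — every quantitative output also
lands in CSV/JSON, and nothing downstream parses an image.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_trace", "plot_frequency_map", "plot_phaseplane"]


def plot_trace(traj, summary, path: Path) -> Path:
    """Voltage trace with the spike threshold and registered crossings."""
    fig, ax = plt.subplots(figsize=(8, 3))
    unit = "s" if traj.model == "minimal" else "ms"
    ax.plot(traj.times, traj.v, lw=0.8, color="k")
    ax.axhline(summary.threshold, color="r", ls="--", lw=0.8, label="threshold")
    if len(summary.crossing_times):
        ax.plot(
            summary.crossing_times,
            np.full_like(summary.crossing_times, summary.threshold),
            "r|",
            ms=10,
        )
    freq = f"{summary.frequency:.2f} Hz" if summary.frequency else summary.regime
    ax.set(xlabel=f"time ({unit})", ylabel="v", title=f"{traj.model}: {freq}")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_frequency_map(fmap, path: Path, ratio_lines=(1 / 30, 1 / 15)) -> Path:
    """Heatmap of firing frequency over the (g_AMPA, g_NMDA) plane."""
    fig, ax = plt.subplots(figsize=(6, 5))
    fr = fmap.frequency
    mesh = ax.pcolormesh(
        fmap.gn_axis, fmap.ga_axis, fr, shading="nearest", cmap="hot"
    )
    fig.colorbar(mesh, ax=ax, label="frequency (Hz)")
    gn = np.asarray(fmap.gn_axis)
    for r in ratio_lines or ():
        ga_line = r * gn
        inside = ga_line <= fmap.ga_axis[-1]
        ax.plot(gn[inside], ga_line[inside], "w-", lw=1)
        if inside.any():
            ax.annotate(
                f"1/{round(1 / r)}",
                (gn[inside][-1], ga_line[inside][-1]),
                color="w",
                fontsize=8,
            )
    ax.set(
        xlabel="NMDA conductance",
        ylabel="AMPA conductance",
        title=f"{fmap.model} firing-frequency map",
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_phaseplane(nullcline_sets, equilibria, path: Path, labels=None) -> Path:
    """Overlay nullcline sets (one per stimulation level) and equilibria."""
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, ns in enumerate(nullcline_sets):
        lbl = labels[i] if labels else None
        if len(ns.v_nullcline):
            pos = ns.v_nullcline[ns.v_nullcline[:, 1] >= 0]
            order = np.argsort(pos[:, 0])
            ax.plot(pos[order, 0], pos[order, 1], ".", ms=2,
                    color=colors[i % len(colors)], label=lbl)
        if i == 0 and len(ns.w_nullcline):
            ax.plot(ns.w_nullcline[:, 0], ns.w_nullcline[:, 1], "k--", lw=0.8,
                    label="w-nullcline")
    for eq in equilibria:
        marker = "o" if eq.stability == "stable" else "x"
        ax.plot(eq.v, eq.w, marker, color="k", ms=6)
    ax.set(xlabel="v", ylabel="w", title="minimal-model phase plane")
    if labels:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
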