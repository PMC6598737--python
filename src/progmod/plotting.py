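"""Figure rendering: spaghetti/hairy-line plots, trajectory panels with
stage histograms, and positional variance heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .preprocess import ID_COLUMNS

__all__ = ["spaghetti_plots", "hairy_line_plots", "trajectory_panel",
           "positional_variance_diagram"]


def _biomarkers(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def spaghetti_plots(table: pd.DataFrame, figdir: Path) -> list[str]:
    """One panel per biomarker/group: each subject's series anchored at
    their baseline visit."""
    written = []
    for group in [g for g in table["group"].unique() if g != "control"]:
        sub = table[table["group"] == group]
        bios = _biomarkers(table)
        ncol = min(4, len(bios))
        nrow = int(np.ceil(len(bios) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow),
                                 squeeze=False)
        for ax, b in zip(axes.flat, bios):
            for _, grp in sub.groupby("subject_id"):
                ax.plot(grp["years_since_baseline"], grp[b], "-o",
                        ms=2, lw=0.7, alpha=0.5)
            ax.set_title(b, fontsize=9)
            ax.set_xlabel("years since baseline", fontsize=8)
            ax.set_ylabel("z", fontsize=8)
        for ax in axes.flat[len(bios):]:
            ax.axis("off")
        fig.suptitle(f"spaghetti — {group}")
        fig.tight_layout()
        path = figdir / f"spaghetti_{group}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(str(path))
    return written


def hairy_line_plots(table: pd.DataFrame, traj: pd.DataFrame, group: str,
                     stages: pd.DataFrame, figdir: Path) -> list[str]:
    """Observed series anchored to the group trajectory: each subject's
    baseline point is placed on the curve at their staged time."""
    stage_map = dict(zip(stages["subject_id"], stages["stage_time"]))
    sub = table[table["group"] == group]
    bios = [b for b in _biomarkers(table) if b in set(traj["biomarker"])]
    ncol = min(4, len(bios))
    nrow = int(np.ceil(len(bios) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow),
                             squeeze=False)
    for ax, b in zip(axes.flat, bios):
        curve = traj[traj["biomarker"] == b]
        ax.plot(curve["time"], curve["z"], "k-", lw=2)
        for sid, grp in sub.groupby("subject_id"):
            if sid not in stage_map:
                continue
            t0 = stage_map[sid]
            ax.plot(t0 + grp["years_since_baseline"], grp[b], "-",
                    lw=0.6, alpha=0.5)
        ax.set_title(b, fontsize=9)
        ax.set_xlabel("years from t0", fontsize=8)
    for ax in axes.flat[len(bios):]:
        ax.axis("off")
    fig.suptitle(f"hairy lines — {group}")
    fig.tight_layout()
    path = figdir / f"hairy_{group}.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return [str(path)]


def trajectory_panel(traj: pd.DataFrame, group: str, figdir: Path,
                     stages: pd.DataFrame | None = None) -> str:
    """All biomarker trajectories on one z-vs-time axis, with the staged
    subject histogram overlaid."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for b, grp in traj.groupby("biomarker"):
        ax.plot(grp["time"], grp["z"], label=b, lw=1.8)
        ax.fill_between(grp["time"], grp["lo95"], grp["hi95"], alpha=0.12)
    if stages is not None and len(stages):
        ax2 = ax.twinx()
        ax2.hist(stages["stage_time"], bins=20, alpha=0.2, color="grey")
        ax2.set_ylabel("subjects staged", fontsize=8)
    ax.set_xlabel("years from t0")
    ax.set_ylabel("z-score vs controls")
    ax.legend(fontsize=7, ncol=2)
    ax.set_title(f"DEM trajectories — {group}")
    fig.tight_layout()
    path = figdir / f"trajectories_{group}.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return str(path)


def positional_variance_diagram(pvd: pd.DataFrame, group: str,
                                figdir: Path) -> str:
    """Heatmap of P(event at position); darker = more probable."""
    fig, ax = plt.subplots(figsize=(0.6 * pvd.shape[1] + 2.4,
                                    0.4 * pvd.shape[0] + 1.6))
    ax.imshow(pvd.to_numpy(), cmap="Greys", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(pvd.shape[1]),
                  [str(i + 1) for i in range(pvd.shape[1])], fontsize=8)
    ax.set_yticks(range(pvd.shape[0]), pvd.index, fontsize=8)
    ax.set_xlabel("position in sequence")
    ax.set_title(f"positional variance — {group}")
    fig.tight_layout()
    path = figdir / f"positional_variance_{group}.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return str(path)
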