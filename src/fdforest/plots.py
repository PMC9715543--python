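"""Matplotlib renderings of the analysis outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from fdforest.importance import VARIABLE_GROUPS, ImportanceReport

GROUP_COLORS = {"forest_dynamics": "0.6", "functional_diversity": "#e6b422",
                "individual_traits": "#4477aa"}


def importance_bars(reports: list[ImportanceReport], path=None):
    """Stacked group-importance bars, one per report (stratum/scenario)."""
    fig, ax = plt.subplots(figsize=(1.6 * len(reports) + 2, 4))
    xs = np.arange(len(reports))
    bottom = np.zeros(len(reports))
    for group in VARIABLE_GROUPS:
        vals = np.array([r.groups[group] for r in reports])
        ax.bar(xs, vals, bottom=bottom, color=GROUP_COLORS[group],
               label=group.replace("_", " "))
        bottom += vals
    ax.set_xticks(xs, [r.stratum for r in reports])
    ax.set_ylabel("normalized importance")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def pdp_lines(curves, path=None):
    """Centred partial-dependence curves, one panel per variable."""
    curves = list(curves)
    fig, axes = plt.subplots(1, len(curves),
                             figsize=(3 * len(curves), 3), squeeze=False)
    for ax, c in zip(axes[0], curves):
        ax.axhline(0.0, color="0.8", lw=0.8)
        ax.plot(c.grid, c.values, color="#4477aa")
        ax.fill_between(c.grid, c.values - c.sds, c.values + c.sds,
                        color="#4477aa", alpha=0.25, lw=0)
        ax.set_xlabel(c.variable)
        ax.set_ylabel("survival probability difference")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def composition_lines(trajectory: pd.DataFrame, path=None):
    """PFT-share trajectories over saved years."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    pft_cols = [c for c in trajectory.columns
                if c not in ("year", "broadleaf", "defined")]
    for c in pft_cols:
        ax.plot(trajectory["year"], trajectory[c], label=c)
    ax.plot(trajectory["year"], trajectory["broadleaf"], "k--",
            label="broadleaf")
    ax.set_xlabel("simulation year")
    ax.set_ylabel("fraction of trees > 5 m")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def trait_histograms(summary_by_year: dict[int, dict], trait: str, path=None):
    """Overlayed per-PFT trait histograms for several years."""
    pfts = sorted({p for s in summary_by_year.values() for p in s})
    fig, axes = plt.subplots(1, max(len(pfts), 1),
                             figsize=(3 * max(len(pfts), 1), 3), squeeze=False)
    for ax, pft in zip(axes[0], pfts):
        for year, summ in summary_by_year.items():
            if pft not in summ:
                continue
            s = summ[pft]
            centers = 0.5 * (s["edges"][:-1] + s["edges"][1:])
            ax.step(centers, s["density"], where="mid", label=str(year))
        ax.set_title(pft, fontsize=9)
        ax.set_xlabel(trait)
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def height_bars(structure: pd.DataFrame, path=None):
    """Height-class counts of living trees."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(structure["height_low"], structure["count"],
           width=0.9 * (structure["height_high"] - structure["height_low"]),
           align="edge", color="0.5")
    ax.set_xlabel("height class (m)")
    ax.set_ylabel("trees")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
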