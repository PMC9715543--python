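"""Descriptive trajectory summaries of simulation runs.

Pure functions of saved snapshots: PFT composition trajectories (including
the combined broadleaf fraction), per-PFT trait distributions comparable
across years, and height-class structure. Fractions count individuals, not
biomass; a biomass weighting is available as an option.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BROADLEAF_PFTS = ("BL-S", "BL-E")


def composition_trajectory(snapshots: dict[int, dict[str, pd.DataFrame]],
                           min_height: float = 5.0,
                           by_biomass: bool = False) -> pd.DataFrame:
    """Per saved year, the fraction of living trees > ``min_height`` in each
    PFT plus the combined broadleaf share.

    ``by_biomass`` weights trees by wood_density * height^2 instead of
    counting individuals. Years without qualifying trees get NaN shares and
    ``defined`` False.
    """
    pfts = sorted({p for tabs in snapshots.values()
                   for p in tabs["trees"]["pft"].unique()})
    rows = []
    for year in sorted(snapshots):
        trees = snapshots[year]["trees"]
        sel = trees[(trees["alive"]) & (trees["height"] > min_height)]
        row = {"year": year}
        if len(sel) == 0:
            row.update({p: np.nan for p in pfts})
            row["broadleaf"] = np.nan
            row["defined"] = False
        else:
            w = (sel["wood_density"] * sel["height"] ** 2 if by_biomass
                 else pd.Series(1.0, index=sel.index))
            total = w.sum()
            for p in pfts:
                row[p] = float(w[sel["pft"] == p].sum() / total)
            row["broadleaf"] = float(sum(row.get(p, 0.0)
                                         for p in BROADLEAF_PFTS if p in pfts))
            row["defined"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def trait_distribution_summary(trees: pd.DataFrame, trait: str,
                               bins: int = 20,
                               bin_range: tuple[float, float] | None = None
                               ) -> dict[str, dict]:
    """Per-PFT binned density and quartiles of one trait.

    Returns {pft: {'edges', 'density', 'q25', 'q50', 'q75', 'n'}}; densities
    are normalized so the bin masses sum to one. Empty PFTs are omitted
    with a log entry. Pass an explicit ``bin_range`` to compare years on
    identical bins.
    """
    if trait not in ("sla", "wood_density", "leaf_longevity"):
        raise ValueError(f"unsupported trait {trait!r}")
    sel = trees[trees["alive"]]
    out = {}
    for pft, grp in sel.groupby("pft"):
        v = grp[trait].to_numpy(float)
        if v.size == 0:
            logger.info("PFT %s empty for trait %s; omitted", pft, trait)
            continue
        counts, edges = np.histogram(v, bins=bins, range=bin_range)
        out[pft] = {
            "edges": edges,
            "density": counts / counts.sum(),
            "q25": float(np.quantile(v, 0.25)),
            "q50": float(np.quantile(v, 0.50)),
            "q75": float(np.quantile(v, 0.75)),
            "n": int(v.size),
        }
    return out


def height_structure(trees: pd.DataFrame, bin_width: float = 5.0
                     ) -> pd.DataFrame:
    """Counts of living trees per height class of ``bin_width`` metres."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sel = trees[trees["alive"]]
    h = sel["height"].to_numpy(float)
    if h.size == 0:
        return pd.DataFrame({"height_low": [], "height_high": [], "count": []})
    n_bins = int(np.floor(h.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(h, bins=edges)
    return pd.DataFrame({"height_low": edges[:-1], "height_high": edges[1:],
                         "count": counts})
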