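"""Functional-diversity indices on per-patch trait clouds.

Each patch's living trees taller than 5 m form a cloud of points in the
3-dimensional trait space (SLA, leaf longevity, wood density), standardized
with site-level statistics so the axes are unit-free. Three community
indices are computed per patch:

* functional richness (FR) -- the volume of the convex hull of the cloud,
  i.e. the extent of occupied trait space;
* functional divergence (FDv) -- how far abundance sits from the trait-space
  gravity centre, in [0, 1];
* functional evenness (FE) -- regularity of point spacing and weights along
  the minimum spanning tree of the cloud, in [0, 1].

FR is strongly right-skewed across patches, so its natural log ln(FR) is
carried alongside. Patches whose clouds are degenerate (fewer than four
distinct points, or coplanar ones) have zero hull volume; they are flagged
and excluded from ln(FR)-based analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import squareform, pdist

TRAIT_COLUMNS = ("sla", "leaf_longevity", "wood_density")


@dataclass(frozen=True)
class TraitStandardizer:
    """Site-level trait means and SDs, fitted once over all analysis trees."""

    means: np.ndarray
    sds: np.ndarray
    names: tuple[str, ...] = TRAIT_COLUMNS

    @classmethod
    def fit(cls, points: np.ndarray,
            names: tuple[str, ...] = TRAIT_COLUMNS) -> "TraitStandardizer":
        points = np.asarray(points, dtype=float)
        means = points.mean(axis=0)
        sds = points.std(axis=0, ddof=0)
        for j, s in enumerate(sds):
            if s <= 0:
                raise ValueError(
                    f"trait {names[j]!r} has zero standard deviation")
        return cls(means, sds, tuple(names))

    def transform(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.means) / self.sds

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sds + self.means


def standardize_traits(points: np.ndarray,
                       stats: TraitStandardizer) -> np.ndarray:
    """Centre and scale each trait column by site-level statistics."""
    return stats.transform(points)


@dataclass
class TraitCloud:
    """Weighted point cloud of one patch in standardized trait space.

    Exact duplicate rows are merged with summed weights, so a community in
    which every individual appears twice yields the identical cloud (and
    identical indices) as the original.
    """

    points: np.ndarray  # (n, d)
    weights: np.ndarray  # (n,), nonnegative, sums to 1

    @classmethod
    def from_points(cls, points: np.ndarray,
                    weights: np.ndarray | None = None) -> "TraitCloud":
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.size == 0 or np.isnan(points).any():
            raise ValueError("cloud must be non-empty without missing values")
        n = len(points)
        w = (np.full(n, 1.0 / n) if weights is None
             else np.asarray(weights, dtype=float))
        if w.shape != (n,) or (w < 0).any():
            raise ValueError("weights must be nonnegative, one per point")
        uniq, inverse = np.unique(points, axis=0, return_inverse=True)
        wu = np.zeros(len(uniq))
        np.add.at(wu, inverse, w)
        wu = wu / wu.sum()
        return cls(uniq, wu)

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class FDIndices:
    """Per-patch index bundle. ``fdv``/``fe`` are NaN when undefined."""

    fr: float  # hull volume, standardized trait units^3
    ln_fr: float  # NaN when fr == 0
    fdv: float
    fe: float
    n_trees: int
    degenerate: bool


def _hull(points: np.ndarray) -> ConvexHull | None:
    if len(points) < points.shape[1] + 1:
        return None
    try:
        return ConvexHull(points)
    except QhullError:
        return None  # coplanar / collinear cloud


def functional_richness(cloud: TraitCloud) -> tuple[float, bool]:
    """Convex-hull volume of the cloud; (0.0, True) for degenerate clouds."""
    hull = _hull(cloud.points)
    if hull is None:
        return 0.0, True
    return float(hull.volume), False


def functional_divergence(cloud: TraitCloud) -> float:
    """Abundance-weighted divergence from the hull's gravity centre.

    With the gravity centre G of the hull vertices and d_i the distance of
    each point to G: dbar is the unweighted mean of d_i, Dd the weighted
    mean deviation, D|d| the weighted mean absolute deviation, and
    FDv = (Dd + dbar) / (D|d| + dbar), in [0, 1]. NaN for degenerate clouds.
    """
    hull = _hull(cloud.points)
    if hull is None:
        return float("nan")
    centre = cloud.points[hull.vertices].mean(axis=0)
    d = np.linalg.norm(cloud.points - centre, axis=1)
    dbar = d.mean()
    dev = d - dbar
    delta_d = float(np.sum(cloud.weights * dev))
    delta_abs = float(np.sum(cloud.weights * np.abs(dev)))
    return (delta_d + dbar) / (delta_abs + dbar)


def functional_evenness(cloud: TraitCloud) -> float:
    """Evenness of weighted branch lengths along the minimum spanning tree.

    Each MST branch (i, j) has weighted length EW = dist / (w_i + w_j);
    partial evennesses PEW are the EW normalized to sum one, and
    FE = (sum_l min(PEW_l, 1/(n-1)) - 1/(n-1)) / (1 - 1/(n-1)).

    Equal to 1 exactly for evenly spaced, equally weighted configurations.
    A two-point cloud is trivially even (1.0); single points give NaN.
    """
    n = cloud.n
    if n < 2:
        return float("nan")
    if n == 2:
        return 1.0
    dist = squareform(pdist(cloud.points))
    mst = minimum_spanning_tree(dist).tocoo()
    ew = mst.data / (cloud.weights[mst.row] + cloud.weights[mst.col])
    total = ew.sum()
    if total == 0:
        return float("nan")
    pew = ew / total
    thr = 1.0 / (n - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def compute_indices(cloud: TraitCloud, n_trees: int | None = None) -> FDIndices:
    """All three indices plus ln(FR) for one cloud.

    ``n_trees`` is the individual count behind the cloud (defaults to the
    number of distinct points).
    """
    fr, degenerate = functional_richness(cloud)
    ln_fr = float(np.log(fr)) if fr > 0 else float("nan")
    fdv = functional_divergence(cloud)
    fe = functional_evenness(cloud)
    return FDIndices(fr=fr, ln_fr=ln_fr, fdv=fdv, fe=fe,
                     n_trees=cloud.n if n_trees is None else int(n_trees),
                     degenerate=degenerate)


def patch_indices(trees: pd.DataFrame, stats: TraitStandardizer,
                  min_height: float = 5.0) -> FDIndices:
    """Indices for one patch's tree table (equal weight per individual).

    Filters to living trees above ``min_height`` before building the cloud.
    A patch with no qualifying trees raises ValueError; a single tree gives
    fr = 0 (degenerate) with NaN divergence/evenness.
    """
    sel = trees[(trees["alive"]) & (trees["height"] > min_height)]
    if len(sel) == 0:
        raise ValueError("patch holds no living trees above the height cutoff")
    pts = standardize_traits(sel[list(TRAIT_COLUMNS)].to_numpy(float), stats)
    return compute_indices(TraitCloud.from_points(pts), n_trees=len(sel))


def snapshot_indices(trees: pd.DataFrame,
                     stats: TraitStandardizer | None = None,
                     min_height: float = 5.0) -> pd.DataFrame:
    """Per-patch index table for one snapshot.

    ``stats`` defaults to site-level statistics fitted over all qualifying
    trees of this snapshot (fit them once at t0 and pass them in to compare
    several years on a common scale).
    """
    sel = trees[(trees["alive"]) & (trees["height"] > min_height)]
    if stats is None:
        stats = TraitStandardizer.fit(sel[list(TRAIT_COLUMNS)].to_numpy(float))
    rows = []
    for patch_id, grp in sel.groupby("patch_id", sort=True):
        pts = standardize_traits(grp[list(TRAIT_COLUMNS)].to_numpy(float), stats)
        idx = compute_indices(TraitCloud.from_points(pts), n_trees=len(grp))
        rows.append({"patch_id": patch_id, "fr": idx.fr, "ln_fr": idx.ln_fr,
                     "fdv": idx.fdv, "fe": idx.fe, "n_trees": idx.n_trees,
                     "degenerate": idx.degenerate})
    return pd.DataFrame(rows)
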