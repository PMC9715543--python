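"""Planted-model survival cohorts with known ground truth.

Generates synthetic survival tables whose label follows a logistic model
p(survive) = sigmoid(b0 + sum_v beta_v * z_v) on standardized covariates,
with marginals shaped like simulator output. Because the coefficients are
known exactly, these cohorts calibrate the importance and
partial-dependence machinery: zero-coefficient covariates must receive
(jointly) negligible importance, monotone effects must yield monotone
centred curves, and effects planted only below a height threshold must
surface only in the understorey stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fdforest.cohort import COVARIATES


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the eight covariates with simulator-like marginals."""
    return pd.DataFrame({
        "sla": rng.uniform(4.0, 45.0, n),
        "wood_density": rng.uniform(0.35, 0.8, n),
        "height_t0": np.clip(5.0 + rng.gamma(2.0, 5.0, n), 5.0, 40.0),
        "ntrees_t0": rng.poisson(16.0, n).astype(float),
        "veg_c_t0": rng.gamma(6.0, 2.5, n),
        "ln_fr_t0": rng.normal(0.0, 1.0, n),
        "fdv_t0": rng.beta(4.0, 2.0, n),
        "fe_t0": rng.beta(5.0, 3.0, n),
    })


def _zscore(x: pd.DataFrame) -> pd.DataFrame:
    return (x - x.mean()) / x.std(ddof=0)


def make_logistic_cohort(n: int, betas: dict[str, float],
                         intercept: float = 0.0, seed: int = 0,
                         site: str = "planted",
                         scenario: str = "reference") -> pd.DataFrame:
    """Cohort whose survival label follows a known logistic model.

    ``betas`` maps covariate column names (subset of the eight predictors)
    to coefficients on the standardized scale; unmentioned covariates have
    coefficient zero and are pure noise.
    """
    unknown = set(betas) - set(COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariates {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    x = _covariates(n, rng)
    z = _zscore(x)
    logit = intercept + sum(b * z[v] for v, b in betas.items())
    p = 1.0 / (1.0 + np.exp(-logit))
    records = x.copy()
    records.insert(0, "survived", rng.random(n) < p)
    records.insert(0, "scenario", scenario)
    records.insert(0, "site", site)
    records.insert(0, "tree_id", np.arange(n))
    records["patch_id"] = np.arange(n) // 20
    return records


def make_height_dependent_cohort(n: int, base_betas: dict[str, float],
                                 understorey_betas: dict[str, float],
                                 threshold: float = 10.0, intercept: float = 0.0,
                                 seed: int = 0) -> pd.DataFrame:
    """Cohort in which an extra coefficient block applies only to trees at
    or below the height threshold (e.g. a diversity effect confined to the
    understorey)."""
    rng = np.random.default_rng(seed)
    x = _covariates(n, rng)
    z = _zscore(x)
    logit = intercept + sum(b * z[v] for v, b in base_betas.items())
    small = (x["height_t0"] <= threshold).to_numpy()
    extra = sum(b * z[v] for v, b in understorey_betas.items())
    logit = logit + np.where(small, extra, 0.0)
    p = 1.0 / (1.0 + np.exp(-logit))
    records = x.copy()
    records.insert(0, "survived", rng.random(n) < p)
    records.insert(0, "scenario", "reference")
    records.insert(0, "site", "planted")
    records.insert(0, "tree_id", np.arange(n))
    records["patch_id"] = np.arange(n) // 20
    return records


def make_mixed_pure_communities(n_rep: int, seed: int = 0) -> pd.DataFrame:
    """Initial tree tables for a paired community experiment.

    Patches 0..n_rep-1 hold pure summergreen-broadleaf communities, patches
    n_rep..2*n_rep-1 mix broadleaf with evergreen needles; every patch has 8
    canopy trees (24-30 m) and 10 understorey trees (2-9 m), so the designs
    are density-matched and differ only in phenological mixture. Feed the
    result to ``run_simulation(..., initial_trees=...)`` with
    ``spin_up_years=0`` to measure complementarity effects directly.
    """
    from fdforest.simulator import leaf_longevity_from_sla

    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(2 * n_rep):
        pure = pid < n_rep
        heights = list(rng.uniform(24.0, 30.0, 8)) + list(rng.uniform(2.0, 9.0, 10))
        for i, h in enumerate(heights):
            if pure or i % 2 == 0:
                pft, phen, slar = "BL-S", "summergreen", (10.0, 45.0)
            else:
                pft, phen, slar = "T-NL", "evergreen-needle", (4.0, 12.0)
            sla = rng.uniform(*slar)
            rows.append({
                "patch_id": pid, "pft": pft, "sla": sla,
                "leaf_longevity": float(leaf_longevity_from_sla(sla, phen)),
                "wood_density": rng.uniform(0.45, 0.6),
                "height": h, "age": 30.0 if h > 20 else 8.0,
            })
    return pd.DataFrame(rows)
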