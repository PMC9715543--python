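"""Survival labelling: build the analysis table from two snapshot years.

A tree enters the analysis if it is alive and taller than 5 m at the first
snapshot (t0); it is labelled a survivor if the same individual is still
alive at the second snapshot (t1), a century later in the standard design.
All covariates -- individual traits, patch dynamics, patch functional
diversity -- are taken from t0 only, so the classifier predicts survival
from initial conditions. Trees at most 5 m tall are saplings and excluded.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

#: Covariate columns of a survival record, in analysis order.
COVARIATES = ("sla", "wood_density", "height_t0", "ntrees_t0", "veg_c_t0",
              "ln_fr_t0", "fdv_t0", "fe_t0")


def label_survival(t0_trees: pd.DataFrame, t1_trees: pd.DataFrame,
                   t0_patches: pd.DataFrame, diversity: pd.DataFrame,
                   min_height: float = 5.0, site: str = "site",
                   scenario: str = "reference") -> pd.DataFrame:
    """One record per living tree > ``min_height`` at t0.

    ``survived`` is True when the tree's id is present and alive at t1. Ids
    present at t1 but not t0 are new recruits and ignored; a duplicated id
    within either snapshot is an error. Record count always equals the
    count of qualifying t0 trees; trees of hull-degenerate patches carry
    NaN ln(FR) and can be removed later with :func:`drop_degenerate_records`.
    """
    for name, df in (("t0", t0_trees), ("t1", t1_trees)):
        if df["tree_id"].duplicated().any():
            raise ValueError(f"duplicated tree id in {name} snapshot")

    sel = t0_trees[(t0_trees["alive"]) & (t0_trees["height"] > min_height)]
    alive_t1 = set(t1_trees.loc[t1_trees["alive"], "tree_id"])

    records = pd.DataFrame({
        "tree_id": sel["tree_id"].to_numpy(),
        "site": site,
        "scenario": scenario,
        "survived": sel["tree_id"].isin(alive_t1).to_numpy(),
        "sla": sel["sla"].to_numpy(float),
        "wood_density": sel["wood_density"].to_numpy(float),
        "height_t0": sel["height"].to_numpy(float),
        "patch_id": sel["patch_id"].to_numpy(),
    })
    patch_cov = t0_patches[["patch_id", "ntrees", "veg_c"]].rename(
        columns={"ntrees": "ntrees_t0", "veg_c": "veg_c_t0"})
    div_cov = diversity[["patch_id", "ln_fr", "fdv", "fe"]].rename(
        columns={"ln_fr": "ln_fr_t0", "fdv": "fdv_t0", "fe": "fe_t0"})
    records = records.merge(patch_cov, on="patch_id", how="left")
    records = records.merge(div_cov, on="patch_id", how="left")
    return records[["tree_id", "site", "scenario", "survived", "patch_id",
                    *COVARIATES]]


def drop_degenerate_records(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove records with incomplete diversity covariates (degenerate
    patches); returns the filtered table and the dropped count."""
    complete = records[list(COVARIATES)].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d records from degenerate patches", n_dropped)
    return records[complete].reset_index(drop=True), n_dropped


def stratify_by_height(records: pd.DataFrame, threshold: float = 10.0
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into understorey (height_t0 <= threshold) and
    canopy (> threshold) strata. Trees exactly at the threshold go to the
    understorey so the split is a deterministic partition."""
    small = records[records["height_t0"] <= threshold].reset_index(drop=True)
    large = records[records["height_t0"] > threshold].reset_index(drop=True)
    return small, large
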