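"""Random-forest survival classification and permutation importance.

Fits an ensemble classifier to predict individual tree survival from eight
t0 covariates, then measures each covariate's permutation importance (mean
decrease in held-out accuracy over repeated column permutations),
normalizes the importances to sum to one, and aggregates them into three
variable groups: individual traits (SLA, wood density, height), forest
dynamics (ntrees, VegC) and functional diversity (ln FR, FDv, FE).

Because mortality rates differ strongly between runs, classes are balanced
by subsampling equal numbers of dead and surviving trees before the 80/20
train/test split. A standard random-forest classifier with held-out
permutation importance is used; the analysis surface is the importance
contrast between variable groups, which is insensitive to the particular
ensemble splitter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_perm_importance
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import train_test_split

from fdforest.cohort import COVARIATES

logger = logging.getLogger(__name__)

#: Short analysis names for the eight predictors, keyed by record column.
PREDICTOR_NAMES = {
    "sla": "sla", "wood_density": "wood_density", "height_t0": "height",
    "ntrees_t0": "ntrees", "veg_c_t0": "veg_c",
    "ln_fr_t0": "ln_fr", "fdv_t0": "fdv", "fe_t0": "fe",
}

VARIABLE_GROUPS = {
    "individual_traits": ("sla", "wood_density", "height"),
    "forest_dynamics": ("ntrees", "veg_c"),
    "functional_diversity": ("ln_fr", "fdv", "fe"),
}


@dataclass(frozen=True)
class RFConfig:
    """Hyperparameters of the survival forest and the importance protocol."""

    n_trees_forest: int = 500  # ntree
    n_split_vars: int = 3  # mtry
    subsample_total: int = 5000
    train_fraction: float = 0.8
    importance_repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.subsample_total % 2:
            raise ValueError("subsample_total must be even")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 1 <= self.n_split_vars <= len(COVARIATES):
            raise ValueError("n_split_vars must be between 1 and the "
                             f"{len(COVARIATES)} predictors")


@dataclass
class ImportanceReport:
    """Normalized per-variable importances with repeat statistics."""

    importances: dict[str, float]  # short name -> normalized mean
    importance_sds: dict[str, float]  # across-repeat SD, same scale
    accuracy: float
    auc: float
    stratum: str = "all"
    n_train: int = 0
    n_test: int = 0

    @property
    def groups(self) -> dict[str, float]:
        return group_importance(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": list(self.importances),
            "importance": list(self.importances.values()),
            "sd": [self.importance_sds[v] for v in self.importances],
            "stratum": self.stratum,
        })


def balanced_subsample(records: pd.DataFrame, total: int,
                       seed: int = 0) -> pd.DataFrame:
    """Draw total/2 survivors and total/2 non-survivors without replacement."""
    rng = np.random.default_rng(seed)
    alive = records[records["survived"]]
    dead = records[~records["survived"]]
    half = total // 2
    if len(alive) < half or len(dead) < half:
        raise ValueError(
            f"need {half} records per class, have {len(alive)} survivors "
            f"and {len(dead)} non-survivors")
    picks = [alive.iloc[rng.choice(len(alive), half, replace=False)],
             dead.iloc[rng.choice(len(dead), half, replace=False)]]
    return pd.concat(picks).reset_index(drop=True)


def split_train_test(subsample: pd.DataFrame, train_fraction: float = 0.8,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, class-stratified train/test split."""
    train, test = train_test_split(
        subsample, train_size=train_fraction,
        stratify=subsample["survived"], random_state=seed)
    return train.reset_index(drop=True), test.reset_index(drop=True)


def _xy(records: pd.DataFrame):
    return records[list(COVARIATES)].to_numpy(float), \
        records["survived"].to_numpy(bool)


def fit_survival_forest(train: pd.DataFrame,
                        config: RFConfig) -> RandomForestClassifier:
    """Fit the ensemble survival classifier; deterministic given the seed."""
    x, y = _xy(train)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are constant")
    model = RandomForestClassifier(
        n_estimators=config.n_trees_forest,
        max_features=config.n_split_vars,
        random_state=config.seed, n_jobs=1)
    model.fit(x, y)
    return model


def predict_survival(model, records: pd.DataFrame) -> np.ndarray:
    """Predicted survival probability per record."""
    x = records[list(COVARIATES)].to_numpy(float)
    return model.predict_proba(x)[:, list(model.classes_).index(True)]


def evaluate(model, test: pd.DataFrame) -> tuple[float, float]:
    """(accuracy, AUC) on held-out records."""
    x, y = _xy(test)
    proba = predict_survival(model, test)
    return (float(accuracy_score(y, proba >= 0.5)),
            float(roc_auc_score(y, proba)))


@dataclass
class TuningResult:
    best_ntree: int
    best_mtry: int
    ntree_trace: pd.DataFrame  # columns ntree, auc
    mtry_trace: pd.DataFrame  # columns mtry, auc


def tune_hyperparameters(train: pd.DataFrame, test: pd.DataFrame,
                         config: RFConfig | None = None) -> TuningResult:
    """Two-stage grid: ntree 50..800 step 50 at mtry = 2, then mtry 2..8 at
    ntree = 500; selection by held-out AUC (first best on ties)."""
    config = config or RFConfig()
    ntrees = list(range(50, 801, 50))
    rows = []
    for nt in ntrees:
        m = fit_survival_forest(train, replace(config, n_trees_forest=nt,
                                               n_split_vars=2))
        rows.append({"ntree": nt, "auc": evaluate(m, test)[1]})
    ntree_trace = pd.DataFrame(rows)
    best_ntree = int(ntree_trace.loc[ntree_trace["auc"].idxmax(), "ntree"])

    rows = []
    for mt in range(2, 9):
        m = fit_survival_forest(train, replace(config, n_trees_forest=500,
                                               n_split_vars=mt))
        rows.append({"mtry": mt, "auc": evaluate(m, test)[1]})
    mtry_trace = pd.DataFrame(rows)
    best_mtry = int(mtry_trace.loc[mtry_trace["auc"].idxmax(), "mtry"])
    return TuningResult(best_ntree, best_mtry, ntree_trace, mtry_trace)


def permutation_importance(model, test: pd.DataFrame, repeats: int = 10,
                           seed: int = 0, stratum: str = "all"
                           ) -> ImportanceReport:
    """Normalized permutation importance on held-out records.

    For each predictor, the drop in accuracy when that column is permuted
    is averaged over ``repeats`` permutations; negative mean drops are
    floored at zero, then the vector is normalized to sum to one (the SDs
    are scaled by the same constant, so they stay comparable).
    """
    x, y = _xy(test)
    res = _sk_perm_importance(model, x, y, scoring="accuracy",
                              n_repeats=repeats, random_state=seed, n_jobs=1)
    raw_mean = np.maximum(res.importances_mean, 0.0)
    total = raw_mean.sum()
    if total <= 0:
        raise ValueError("no predictor shows positive permutation importance")
    acc, auc = evaluate(model, test)
    short = [PREDICTOR_NAMES[c] for c in COVARIATES]
    return ImportanceReport(
        importances=dict(zip(short, raw_mean / total)),
        importance_sds=dict(zip(short, res.importances_std / total)),
        accuracy=acc, auc=auc, stratum=stratum,
        n_test=len(test))


def group_importance(report: ImportanceReport) -> dict[str, float]:
    """Sum normalized importances into the three variable groups."""
    return {g: float(sum(report.importances[v] for v in names))
            for g, names in VARIABLE_GROUPS.items()}


def run_importance_pipeline(records: pd.DataFrame,
                            config: RFConfig | None = None,
                            stratum: str = "all") -> ImportanceReport:
    """Balanced subsample -> stratified split -> fit -> permutation
    importance, with per-stage seeds derived from ``config.seed``."""
    config = config or RFConfig()
    sub = balanced_subsample(records, config.subsample_total, seed=config.seed)
    train, test = split_train_test(sub, config.train_fraction,
                                   seed=config.seed + 1)
    model = fit_survival_forest(train, config)
    report = permutation_importance(model, test,
                                    repeats=config.importance_repeats,
                                    seed=config.seed + 2, stratum=stratum)
    report.n_train = len(train)
    return report


def feasible_total(records: pd.DataFrame, requested: int) -> int:
    """Largest even balanced-subsample size the class counts allow, capped
    at the requested total."""
    smallest = int(min(records["survived"].sum(),
                       (~records["survived"]).sum()))
    return min(requested, 2 * smallest)


def stratified_importance(records: pd.DataFrame, threshold: float = 10.0,
                          config: RFConfig | None = None
                          ) -> dict[str, ImportanceReport]:
    """Run the full pipeline independently per height stratum.

    The subsample total is reduced (and logged) for a stratum whose class
    counts cannot support the configured total; each stratum uses its own
    derived seed so the runs are independent.
    """
    from fdforest.cohort import stratify_by_height

    config = config or RFConfig()
    small, large = stratify_by_height(records, threshold)
    reports = {}
    for name, subset, offset in (("small", small, 1000),
                                 ("large", large, 2000)):
        if len(subset) == 0:
            raise ValueError(f"stratum {name!r} is empty")
        total = feasible_total(subset, config.subsample_total)
        if total < config.subsample_total:
            logger.info("stratum %s: subsample reduced to %d", name, total)
        cfg = replace(config, subsample_total=total,
                      seed=config.seed + offset)
        reports[name] = run_importance_pipeline(subset, cfg, stratum=name)
    return reports
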