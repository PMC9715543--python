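"""Partial dependence and the combined functional-diversity survival effect.

A partial-dependence curve answers: holding all other covariates at their
empirical joint distribution, how does fixing one covariate change the mean
predicted survival probability? Curves are centred on the mean prediction
of the unmodified sample, so a value above zero reads directly as an
additional survival probability contributed by that covariate value.

The headline statistic is the additional survival probability a tree gains
from growing in a functionally diverse community -- high functional
richness, high divergence and low evenness. It is assembled by averaging
each index's centred partial dependence over the relevant 10% tail of the
index's initial (t0) distribution and summing the three tail effects; the
standard deviations combine in quadrature (independent-error propagation),
and site-level effects average the same way across sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fdforest.cohort import COVARIATES
from fdforest.importance import predict_survival


@dataclass
class PDPCurve:
    """Centred partial dependence of one covariate on a fixed grid."""

    variable: str
    grid: np.ndarray  # strictly increasing, covariate units
    values: np.ndarray  # centred mean predicted survival probability
    sds: np.ndarray  # sampling SD of the mean, per grid value
    n_sample: int
    baseline: float  # mean prediction over the unmodified sample
    extrapolated: np.ndarray  # True where grid leaves the observed range

    def __call__(self, x) -> np.ndarray:
        """Linear interpolation of the centred curve."""
        return np.interp(np.asarray(x, dtype=float), self.grid, self.values)


@dataclass
class TailEffect:
    """Mean +/- SD of centred partial dependence over one distribution tail."""

    variable: str
    tail: str  # 'upper' | 'lower'
    mean: float
    sd: float
    n: int


@dataclass
class EffectEstimate:
    """Combined functional-diversity effect for one site and scenario."""

    site: str
    scenario: str
    ln_fr_upper: TailEffect
    fdv_upper: TailEffect
    fe_lower: TailEffect
    mean: float
    sd: float


def default_grid(values: np.ndarray, n_grid: int = 50,
                 q_low: float = 0.01, q_high: float = 0.99) -> np.ndarray:
    """Evenly spaced grid between inner percentiles of the observed values,
    avoiding extrapolation artefacts at the extremes."""
    lo, hi = np.nanquantile(np.asarray(values, dtype=float), [q_low, q_high])
    return np.linspace(lo, hi, n_grid)


def partial_dependence(model, records: pd.DataFrame, variable: str,
                       grid: np.ndarray | None = None, n_sample: int = 1500,
                       seed: int = 0) -> PDPCurve:
    """Centred partial-dependence curve of one predictor.

    ``n_sample`` records are drawn (without replacement when possible);
    for each grid value the variable column is overwritten and the model's
    mean predicted survival probability recorded, minus the mean prediction
    over the unmodified sample. The per-grid SD is the across-record SD of
    predictions divided by sqrt(n_sample).
    """
    if variable not in COVARIATES:
        raise ValueError(f"unknown predictor {variable!r}")
    rng = np.random.default_rng(seed)
    n = min(n_sample, len(records))
    sample = records.iloc[rng.choice(len(records), n, replace=False)]
    sample = sample.reset_index(drop=True)

    obs = records[variable].to_numpy(float)
    if grid is None:
        grid = default_grid(obs)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    baseline = float(predict_survival(model, sample).mean())
    values = np.empty(grid.size)
    sds = np.empty(grid.size)
    work = sample.copy()
    for i, g in enumerate(grid):
        work[variable] = g
        proba = predict_survival(model, work)
        values[i] = proba.mean() - baseline
        sds[i] = proba.std(ddof=0) / np.sqrt(n)

    extrapolated = (grid < np.nanmin(obs)) | (grid > np.nanmax(obs))
    return PDPCurve(variable=variable, grid=grid, values=values, sds=sds,
                    n_sample=n, baseline=baseline, extrapolated=extrapolated)


def tail_effect(pdp: PDPCurve, distribution: np.ndarray, tail: str,
                q: float = 0.10) -> TailEffect:
    """Average the centred curve over one tail of the initial distribution.

    ``distribution`` holds the variable's values over all analysis trees at
    t0; the upper (lower) tail contains the records above (below) the
    1-q (q) quantile. The effect is the mean interpolated curve value over
    those records, its SD the across-record SD of the same values.
    """
    dist = np.asarray(distribution, dtype=float)
    dist = dist[~np.isnan(dist)]
    if dist.size == 0 or np.ptp(dist) == 0:
        raise ValueError("degenerate variable distribution")
    if tail == "upper":
        members = dist[dist >= np.quantile(dist, 1.0 - q)]
    elif tail == "lower":
        members = dist[dist <= np.quantile(dist, q)]
    else:
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    if members.size == 0:
        raise ValueError("empty tail")
    vals = pdp(members)
    sd = float(vals.std(ddof=1)) if members.size > 1 else 0.0
    return TailEffect(variable=pdp.variable, tail=tail,
                      mean=float(vals.mean()), sd=sd, n=int(members.size))


def combined_fd_effect(ln_fr_upper: TailEffect, fdv_upper: TailEffect,
                       fe_lower: TailEffect, site: str = "site",
                       scenario: str = "reference") -> EffectEstimate:
    """Sum the three tail effects; SDs combine in quadrature."""
    effects = (ln_fr_upper, fdv_upper, fe_lower)
    mean = float(sum(e.mean for e in effects))
    sd = float(np.sqrt(sum(e.sd ** 2 for e in effects)))
    return EffectEstimate(site=site, scenario=scenario,
                          ln_fr_upper=ln_fr_upper, fdv_upper=fdv_upper,
                          fe_lower=fe_lower, mean=mean, sd=sd)


def fd_effect_for_records(model, records: pd.DataFrame, n_sample: int = 1500,
                          seed: int = 0, q: float = 0.10,
                          site: str = "site", scenario: str = "reference"
                          ) -> EffectEstimate:
    """Convenience: PDPs and tail effects of the three diversity indices
    (high ln FR, high FDv, low FE) for one record table."""
    parts = {}
    for i, (var, tail) in enumerate(
            (("ln_fr_t0", "upper"), ("fdv_t0", "upper"), ("fe_t0", "lower"))):
        pdp = partial_dependence(model, records, var, n_sample=n_sample,
                                 seed=seed + i)
        parts[(var, tail)] = tail_effect(
            pdp, records[var].to_numpy(float), tail, q=q)
    return combined_fd_effect(parts[("ln_fr_t0", "upper")],
                              parts[("fdv_t0", "upper")],
                              parts[("fe_t0", "lower")],
                              site=site, scenario=scenario)


def cross_site_mean(means, sds) -> tuple[float, float]:
    """Mean of per-site effects with error propagation.

    mean = (1/n) sum(means); sd = sqrt(sum(sds^2)) / n, the SD of a mean of
    independent quantities with the given SDs.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != sds.shape or means.ndim != 1 or means.size == 0:
        raise ValueError("means and sds must be equal-length 1-D sequences")
    n = means.size
    return float(means.mean()), float(np.sqrt(np.sum(sds ** 2)) / n)
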