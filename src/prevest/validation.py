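"""Performance metrics for the simulation study.

Given the long estimates table (one row per dataset and method) and the
scenario table, this module computes

* estimation errors (estimate minus true prevalence), carrying the
  case label for subgroup analysis,
* per-scenario interval coverage (fraction of retained replicates whose
  interval contains the true prevalence),
* interval lengths by method and case,
* equal-variance Deming (orthogonal) regression with a jackknife slope CI
  and the Pearson correlation of the same pairs,
* an ordinary least-squares regression of the estimation error on the
  z-transformed statistical and design parameters and all their pairwise
  interactions, per estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DemingFit",
    "estimation_errors",
    "coverage_by_scenario",
    "interval_lengths",
    "deming_fit",
    "residual_error_regression",
]

DESIGN_VARS = ["pi_true", "se_true", "sp_true", "n", "n_se", "n_sp"]


def _join(estimates: pd.DataFrame, scenarios: pd.DataFrame) -> pd.DataFrame:
    merged = estimates.merge(
        scenarios[["scenario_id", "pi_true", "se_true", "sp_true", "n", "n_se", "n_sp"]],
        on="scenario_id", how="left", validate="many_to_one",
    )
    if merged["pi_true"].isna().any():
        raise ValueError("estimates reference scenario_ids missing from the scenario table")
    return merged


def estimation_errors(estimates: pd.DataFrame, scenarios: pd.DataFrame) -> pd.DataFrame:
    """Per-dataset estimation error, estimate - true prevalence.

    Returns columns scenario_id, replicate_id, method, error, case.
    """
    merged = _join(estimates, scenarios)
    out = merged[["scenario_id", "replicate_id", "method"]].copy()
    out["error"] = merged["point"] - merged["pi_true"]
    if "case" in merged.columns:
        out["case"] = merged["case"]
    return out


def coverage_by_scenario(estimates: pd.DataFrame, scenarios: pd.DataFrame) -> pd.DataFrame:
    """Fraction of replicates whose interval contains the true prevalence.

    Excluded replicates never reach the estimates table, so the denominator
    is the number of retained replicates of the scenario.
    """
    merged = _join(estimates, scenarios)
    merged = merged[merged["lower"].notna() & merged["upper"].notna()]
    covered = (merged["lower"] <= merged["pi_true"]) & (merged["pi_true"] <= merged["upper"])
    g = merged.assign(covered=covered).groupby(["scenario_id", "method"], sort=True)
    out = g.agg(coverage=("covered", "mean"), n_replicates_used=("covered", "size"))
    return out.reset_index()


def interval_lengths(estimates: pd.DataFrame) -> pd.DataFrame:
    """Interval length (upper - lower) per dataset, with method and case."""
    out = estimates[["scenario_id", "replicate_id", "method"]].copy()
    out["length"] = estimates["upper"] - estimates["lower"]
    if "case" in estimates.columns:
        out["case"] = estimates["case"]
    return out


def exact_interval_coverage_by_scenario(data: pd.DataFrame, scenarios: pd.DataFrame,
                                        ordering: str, level: float = 0.95) -> pd.DataFrame:
    """Per-scenario coverage of a transformed exact interval, by test inversion.

    The prevalence-scale Sterne or Blaker interval covers the true prevalence
    iff the exact test of the apparent prevalence implied by it,
    a* = (1 - sp_hat) + pi_true * (se_hat - (1 - sp_hat)), is not rejected --
    so coverage can be computed from one p-value per dataset without
    constructing the interval (the event that a* lands exactly on an interval
    endpoint has probability zero).
    """
    from . import frequentist as fq

    d = _join(data[data["case"] != "excluded"], scenarios)
    alpha = 1.0 - level
    rows = []
    for sid, g in d.groupby("scenario_id", sort=True):
        n = int(g["n"].iloc[0])
        astar = ((1.0 - g["sp_hat"]) + g["pi_true"] * (g["se_hat"] - (1.0 - g["sp_hat"]))).to_numpy()
        pv = fq.exact_test_pvalue(g["x"].to_numpy(), n, astar, ordering)
        rows.append({"scenario_id": sid, "method": ordering,
                     "coverage": float(np.mean(np.atleast_1d(pv) > alpha)),
                     "n_replicates_used": len(g)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DemingFit:
    """Equal-variance Deming (orthogonal) regression fit."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    r: float
    n: int


def _deming_slope(sxx: float, syy: float, sxy: float, variance_ratio: float) -> float:
    # errors-in-variables slope; variance_ratio = var(err_y) / var(err_x)
    d = syy - variance_ratio * sxx
    return (d + np.sqrt(d * d + 4.0 * variance_ratio * sxy * sxy)) / (2.0 * sxy)


def deming_fit(xs, ys, variance_ratio: float = 1.0, level: float = 0.95) -> DemingFit:
    """Deming regression of ys on xs minimising squared orthogonal distances.

    With ``variance_ratio`` 1 this is orthogonal regression.  The slope CI is
    a leave-one-out jackknife (deterministic given the data); the Pearson
    correlation of the same pairs is reported alongside.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("deming_fit needs two equal-length vectors of >= 3 points")
    n = len(x)
    mx, my = x.mean(), y.mean()
    sxx = np.sum((x - mx) ** 2)
    syy = np.sum((y - my) ** 2)
    sxy = np.sum((x - mx) * (y - my))
    if sxy == 0.0:
        raise ValueError("zero covariance: Deming slope undefined")
    slope = _deming_slope(sxx, syy, sxy, variance_ratio)
    intercept = my - slope * mx

    # leave-one-out jackknife on the slope, via downdated moment sums
    sx, sy = x.sum(), y.sum()
    sxx_r, syy_r, sxy_r = np.sum(x * x), np.sum(y * y), np.sum(x * y)
    m = n - 1
    mx_i = (sx - x) / m
    my_i = (sy - y) / m
    sxx_i = (sxx_r - x * x) - m * mx_i**2
    syy_i = (syy_r - y * y) - m * my_i**2
    sxy_i = (sxy_r - x * y) - m * mx_i * my_i
    with np.errstate(divide="ignore", invalid="ignore"):
        d = syy_i - variance_ratio * sxx_i
        slopes_i = (d + np.sqrt(d * d + 4.0 * variance_ratio * sxy_i**2)) / (2.0 * sxy_i)
    ok = np.isfinite(slopes_i)
    theta = slopes_i[ok]
    k = theta.size
    se = np.sqrt((k - 1) / k * np.sum((theta - theta.mean()) ** 2)) if k > 1 else np.nan
    z = stats.norm.ppf(0.5 + level / 2.0)
    r = float(np.corrcoef(x, y)[0, 1])
    return DemingFit(float(slope), float(intercept),
                     (float(slope - z * se), float(slope + z * se)), r, n)


def residual_error_regression(errors: pd.DataFrame, scenarios: pd.DataFrame) -> pd.DataFrame:
    """OLS of estimation error on standardized truth/design variables.

    Per estimation method, regresses the error on the z-transformed
    (pi_true, se_true, sp_true, n, n_se, n_sp) plus all 15 pairwise
    interactions (22 coefficients with the intercept).  Returns a tidy table
    with columns method, term, coef, std_err, pvalue, r_squared (the model
    R^2 repeated on each of its rows).
    """
    merged = _join(errors, scenarios)
    rows = []
    for method, grp in merged.groupby("method", sort=True):
        zs = {}
        for v in DESIGN_VARS:
            col = grp[v].to_numpy(dtype=float)
            sd = col.std(ddof=1)
            zs[v] = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        X = pd.DataFrame(zs, index=grp.index)
        for a, b in combinations(DESIGN_VARS, 2):
            X[f"{a}:{b}"] = X[a] * X[b]
        y = grp["error"].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            # degenerate response: all coefficients zero, R^2 zero by convention
            terms = ["const"] + list(X.columns)
            for t in terms:
                rows.append({"method": method, "term": t, "coef": 0.0,
                             "std_err": np.nan, "pvalue": np.nan, "r_squared": 0.0})
            continue
        exog = sm.add_constant(X)
        fit = sm.OLS(y, exog).fit()
        rank_deficient = np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]
        for t in exog.columns:
            rows.append({
                "method": method, "term": t, "coef": fit.params[t],
                "std_err": fit.bse[t], "pvalue": fit.pvalues[t],
                "r_squared": fit.rsquared,
                **({"rank_deficient": True} if rank_deficient else {}),
            })
    return pd.DataFrame(rows)
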