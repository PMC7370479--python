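"""Rogan-Gladen prevalence estimation and 95% confidence intervals.

The misclassification-adjusted (Rogan-Gladen) point estimate is

    RGE = (AP_hat - (1 - Sp_hat)) / (Se_hat - (1 - Sp_hat)),

with AP_hat = x/n the observed test-positive proportion and Se_hat, Sp_hat
the validation-study MLEs.  The raw value may fall outside [0, 1]; reported
points are truncated to the unit interval.

Five interval constructions are provided:

* ``clopper_pearson``, ``sterne``, ``blaker`` -- exact binomial intervals for
  the apparent prevalence (equal-tailed quantile inversion for
  Clopper-Pearson; inversion of the minimum-likelihood and combined-tails
  exact tests for Sterne and Blaker), linearly mapped to the prevalence
  scale treating Se_hat and Sp_hat as known.
* ``wald_rogan_gladen`` -- normal approximation around the truncated point
  estimate with the delta-method variance that propagates the uncertainty of
  all three binomials.
* ``lang_reiczigel`` -- an adjusted Wald-type interval: pseudo-observations
  are added to the three binomials (an Agresti-Coull z^2/2 adjustment for
  the application sample; Beta(1,1) updating, i.e. +1 success / +1 failure,
  for the validation samples), the adjusted Rogan-Gladen point is formed,
  and a delta-method interval with adjusted denominators is truncated to
  [0, 1].

Sterne acceptance regions can in principle be non-contiguous; the interval
returned is the enclosing interval of the acceptance set, located by a
coarse scan plus bisection to 1e-8 on the binomial parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "IntervalEstimate",
    "LangReiczigelAdjustment",
    "rogan_gladen",
    "truncate_unit",
    "exact_binomial_ci",
    "clopper_pearson_interval",
    "sterne_interval",
    "blaker_interval",
    "exact_test_pvalue",
    "transform_ap_interval",
    "wald_rogan_gladen_ci",
    "lang_reiczigel_ci",
    "FREQUENTIST_METHODS",
]

FREQUENTIST_METHODS = (
    "clopper_pearson",
    "sterne",
    "blaker",
    "wald_rogan_gladen",
    "lang_reiczigel",
)

_BISECT_TOL = 1e-8
_PMF_TIE_REL = 1e-10  # relative tolerance for pmf ties in the minlike ordering


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with a two-sided interval on the prevalence scale."""

    method: str
    point: float
    lower: float
    upper: float
    level: float = 0.95
    point_raw: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError("interval must satisfy 0 <= lower <= upper <= 1")

    @property
    def length(self) -> float:
        return self.upper - self.lower


def rogan_gladen(ap_hat, se_hat, sp_hat):
    """Raw (non-truncated) Rogan-Gladen estimate; may fall outside [0, 1]."""
    ap_hat = np.asarray(ap_hat, dtype=float)
    se_hat = np.asarray(se_hat, dtype=float)
    sp_hat = np.asarray(sp_hat, dtype=float)
    fp = 1.0 - sp_hat  # written so boundary cases match the case classification
    denom = se_hat - fp
    if np.any(denom == 0.0):
        raise ZeroDivisionError("se_hat + sp_hat = 1: Rogan-Gladen estimate undefined")
    out = (ap_hat - fp) / denom
    return float(out) if out.ndim == 0 else out


def truncate_unit(v):
    """Clamp to the unit interval [0, 1]."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("truncate_unit requires finite input")
    out = np.minimum(np.maximum(v, 0.0), 1.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# exact binomial intervals for the apparent prevalence
# ---------------------------------------------------------------------------

def clopper_pearson_interval(x, n, level: float = 0.95):
    """Equal-tailed exact binomial interval via Beta quantile inversion.

    Vectorised; endpoints are 0 at x=0 and 1 at x=n.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    alpha = 1.0 - level
    lower = np.where(x > 0, stats.beta.ppf(alpha / 2.0, x, n - x + 1.0), 0.0)
    upper = np.where(x < n, stats.beta.ppf(1.0 - alpha / 2.0, x + 1.0, n - x), 1.0)
    if lower.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def _pmf_matrix(n: int, p: np.ndarray) -> np.ndarray:
    k = np.arange(n + 1)
    return stats.binom.pmf(k[None, :], n, np.asarray(p, dtype=float)[:, None])


def exact_test_pvalue(x, n: int, p, ordering: str):
    """Exact two-sided binomial test p-value under the given ordering.

    ``sterne``: minimum-likelihood ordering -- the p-value is the total
    probability of outcomes no more likely than the observed one.
    ``blaker``: combined-tails ordering -- the smaller tail plus the largest
    attainable opposite-tail probability not exceeding it.

    ``x`` and ``p`` may be arrays of equal length (``n`` scalar); used both
    for interval inversion and for coverage checks without constructing the
    interval.
    """
    x = np.atleast_1d(np.asarray(x, dtype=int))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    x, p = np.broadcast_arrays(x, p)
    pmf = _pmf_matrix(int(n), p)
    rows = np.arange(len(x))
    fx = pmf[rows, x]
    if ordering == "sterne":
        mask = pmf <= fx[:, None] * (1.0 + _PMF_TIE_REL)
        pv = np.sum(pmf * mask, axis=1)
    elif ordering == "blaker":
        cdf = np.cumsum(pmf, axis=1)
        cdf[:, -1] = 1.0
        sf = 1.0 - cdf + pmf  # P(X >= k)
        p_lo = cdf[rows, x]
        p_hi = sf[rows, x]
        # opposite-tail contribution: largest attainable tail prob <= own tail
        tol = 1.0 + 1e-12
        a1 = np.empty(len(x))
        a2 = np.empty(len(x))
        for i in rows:  # n+1-length searches; vector length is modest
            a1[i] = p_hi[i] + _largest_leq(cdf[i, : x[i]], p_hi[i] * tol)
            a2[i] = p_lo[i] + _largest_leq(sf[i, x[i] + 1 :], p_lo[i] * tol)
        pv = np.minimum(a1, a2)
    else:
        raise ValueError(f"unknown ordering: {ordering!r}")
    pv = np.minimum(pv, 1.0)
    return float(pv[0]) if pv.shape == (1,) else pv


def _largest_leq(sorted_or_not: np.ndarray, bound: float) -> float:
    vals = sorted_or_not[sorted_or_not <= bound]
    return float(vals.max()) if vals.size else 0.0


def _invert_test(x: int, n: int, level: float, ordering: str) -> tuple[float, float]:
    """Enclosing interval of {p : p-value(x, n, p) > alpha} by scan + bisection."""
    alpha = 1.0 - level
    mode = x / n if n else 0.5

    def accept(p: float) -> bool:
        if p <= 0.0:
            return x == 0
        if p >= 1.0:
            return x == n
        return exact_test_pvalue(x, n, p, ordering) > alpha

    def edge(lo: float, hi: float, want_first: bool) -> float:
        # indicator goes False->True across [lo, hi] if want_first else True->False
        grid = np.linspace(lo, hi, 129)
        acc = np.array([accept(g) for g in grid])
        if want_first:
            idx = int(np.argmax(acc))  # first accepted grid point
            a, b = grid[max(idx - 1, 0)], grid[idx]  # a rejected, b accepted
        else:
            idx = len(acc) - 1 - int(np.argmax(acc[::-1]))  # last accepted
            a, b = grid[idx], grid[min(idx + 1, len(grid) - 1)]  # a accepted, b rejected
        while b - a > _BISECT_TOL:
            m = 0.5 * (a + b)
            if accept(m) == want_first:
                b = m
            else:
                a = m
        return 0.5 * (a + b)

    lower = 0.0 if x == 0 else edge(0.0, mode, want_first=True)
    upper = 1.0 if x == n else edge(mode, 1.0, want_first=False)
    return lower, upper


def sterne_interval(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact interval inverting the minimum-likelihood-ordering test."""
    _check_xn(x, n)
    return _invert_test(int(x), int(n), level, "sterne")


def blaker_interval(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact interval inverting the combined-tails (acceptability) test."""
    _check_xn(x, n)
    return _invert_test(int(x), int(n), level, "blaker")


def _check_xn(x, n) -> None:
    if not (0 <= x <= n) or n < 1:
        raise ValueError("require 0 <= x <= n with n >= 1")


def exact_binomial_ci(x: int, n: int, level: float = 0.95, ordering: str = "clopper_pearson"):
    """Exact binomial interval for the apparent prevalence, by ordering name."""
    _check_xn(x, n)
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if ordering == "clopper_pearson":
        return clopper_pearson_interval(x, n, level)
    if ordering in ("sterne", "blaker"):
        return _invert_test(int(x), int(n), level, ordering)
    raise ValueError(f"unknown ordering: {ordering!r}")


def transform_ap_interval(ci_ap, se_hat: float, sp_hat: float, level: float = 0.95,
                          method: str = "clopper_pearson", point_raw: float | None = None) -> IntervalEstimate:
    """Map an apparent-prevalence interval to the prevalence scale.

    Applies the (increasing) Rogan-Gladen linear map to both endpoints with
    Se_hat, Sp_hat treated as known, then truncates to [0, 1].
    """
    fp = 1.0 - sp_hat
    denom = se_hat - fp
    if denom <= 0.0:
        raise ValueError("se_hat + sp_hat must exceed 1 to adjust for misclassification")
    lo, hi = ci_ap
    lower = truncate_unit((lo - fp) / denom)
    upper = truncate_unit((hi - fp) / denom)
    point = None if point_raw is None else truncate_unit(point_raw)
    return IntervalEstimate(method, point if point is not None else np.nan,
                            lower, upper, level, point_raw)


# ---------------------------------------------------------------------------
# Wald-type intervals
# ---------------------------------------------------------------------------

def _wald_rg_arrays(ap_hat, se_hat, sp_hat, n, n_se, n_sp, level,
                    include_validation_uncertainty=False):
    z = stats.norm.ppf(0.5 + level / 2.0)
    fp = 1.0 - sp_hat
    denom = se_hat - fp
    raw = (ap_hat - fp) / denom
    point = np.clip(raw, 0.0, 1.0)
    var = ap_hat * (1.0 - ap_hat) / n
    if include_validation_uncertainty:
        var = var + (point**2 * se_hat * (1.0 - se_hat) / n_se
                     + (1.0 - point) ** 2 * sp_hat * (1.0 - sp_hat) / n_sp)
    var = var / denom**2
    half = z * np.sqrt(var)
    return raw, point, np.clip(point - half, 0.0, 1.0), np.clip(point + half, 0.0, 1.0)


def wald_rogan_gladen_ci(m, sizes, level: float = 0.95,
                         include_validation_uncertainty: bool = False) -> IntervalEstimate:
    """Normal-approximation (Wald) interval around the truncated point estimate.

    ``m`` carries se_hat / sp_hat / ap_hat; ``sizes`` is (n, n_se, n_sp).
    By default the binomial variance of the apparent prevalence is mapped
    through the misclassification adjustment with Se_hat and Sp_hat treated
    as known -- the construction used in the traditional-method comparison,
    and one that, like the exact intervals on the AP scale, markedly
    under-covers the true prevalence.  With
    ``include_validation_uncertainty=True`` the full delta-method variance
    adds the validation-study binomial terms (weights evaluated at the
    truncated point estimate).
    """
    n, n_se, n_sp = sizes
    if m.se_hat + m.sp_hat - 1.0 <= 0.0:
        raise ValueError("se_hat + sp_hat must exceed 1")
    raw, point, lo, hi = _wald_rg_arrays(
        np.float64(m.ap_hat), np.float64(m.se_hat), np.float64(m.sp_hat), n, n_se, n_sp,
        level, include_validation_uncertainty,
    )
    return IntervalEstimate("wald_rogan_gladen", float(point), float(lo), float(hi), level, float(raw))


@dataclass(frozen=True)
class LangReiczigelAdjustment:
    """Pseudo-observation constants of the adjusted Wald interval.

    ``ap_add`` successes and failures are added to the application sample
    (default z^2/2, the Agresti-Coull adjustment at the working level);
    ``se_add`` / ``sp_add`` to the validation samples (default 1, i.e.
    Beta(1,1) posterior-mean updating).  Isolated here so the constants can
    be changed without touching callers.
    """

    ap_add: float | None = None  # None -> z^2/2 at the working level
    se_add: float = 1.0
    sp_add: float = 1.0

    def resolved_ap_add(self, z: float) -> float:
        return 0.5 * z * z if self.ap_add is None else self.ap_add


def _lang_reiczigel_arrays(x, x_se, x_sp, n, n_se, n_sp, level,
                           adj: LangReiczigelAdjustment):
    z = stats.norm.ppf(0.5 + level / 2.0)
    a = adj.resolved_ap_add(z)
    n_adj = n + 2.0 * a
    nse_adj = n_se + 2.0 * adj.se_add
    nsp_adj = n_sp + 2.0 * adj.sp_add
    ap = (x + a) / n_adj
    se = (x_se + adj.se_add) / nse_adj
    sp = (x_sp + adj.sp_add) / nsp_adj
    denom = se + sp - 1.0
    raw = (ap - (1.0 - sp)) / denom
    point = np.clip(raw, 0.0, 1.0)
    var = (
        ap * (1.0 - ap) / n_adj
        + point**2 * se * (1.0 - se) / nse_adj
        + (1.0 - point) ** 2 * sp * (1.0 - sp) / nsp_adj
    ) / denom**2
    half = z * np.sqrt(np.maximum(var, 0.0))
    lo = np.clip(point - half, 0.0, 1.0)
    hi = np.clip(point + half, 0.0, 1.0)
    return denom, raw, point, lo, hi


def lang_reiczigel_ci(c, sizes, level: float = 0.95,
                      adjustment: LangReiczigelAdjustment = LangReiczigelAdjustment()) -> IntervalEstimate:
    """Adjusted Wald-type interval for prevalence (Lang-Reiczigel).

    ``c`` carries counts x / x_se / x_sp; ``sizes`` is (n, n_se, n_sp).
    """
    n, n_se, n_sp = sizes
    denom, raw, point, lo, hi = _lang_reiczigel_arrays(
        np.float64(c.x), np.float64(c.x_se), np.float64(c.x_sp), n, n_se, n_sp, level, adjustment
    )
    if denom <= 0.0:
        raise ValueError("adjusted se + sp must exceed 1")
    return IntervalEstimate("lang_reiczigel", float(point), float(lo), float(hi), level, float(raw))
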