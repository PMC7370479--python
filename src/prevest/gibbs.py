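"""Bayesian prevalence estimation under misclassification.

Model: pi ~ Beta(a_pi, b_pi); Se ~ Beta(a_se, b_se); Sp ~ Beta(a_sp, b_sp);
x ~ Binomial(n, Se*pi + (1-Sp)*(1-pi)).  The default priors are the uniform
Beta(1, 1) for the prevalence and validation-informed priors
Beta(x_se+1, n_se-x_se+1) / Beta(x_sp+1, n_sp-x_sp+1) for sensitivity and
specificity, i.e. Beta(1, 1) updated with the validation counts.

The posterior is sampled by data augmentation: introducing the latent number
of truly diseased among the x test-positives (T1) and among the n-x
test-negatives (T2) makes every full conditional conjugate:

    T1 | .  ~ Binomial(x,     pi*Se / (pi*Se + (1-pi)*(1-Sp)))
    T2 | .  ~ Binomial(n - x, pi*(1-Se) / (pi*(1-Se) + (1-pi)*Sp))
    pi | .  ~ Beta(a_pi + T1 + T2,  b_pi + n - T1 - T2)
    Se | .  ~ Beta(a_se + T1,       b_se + T2)
    Sp | .  ~ Beta(a_sp + n-x-T2,   b_sp + x-T1)

This pure-Gibbs scheme has no tuning parameters and vectorises across chains
and across thousands of datasets, which is what makes the simulation study
feasible.  Convergence is monitored with the Gelman-Rubin potential scale
reduction factor (PSRF) on the prevalence; a run failing the threshold is
re-run once with doubled retained length and flagged if it still fails.

Point estimate: posterior mean of the pooled chains (the minimum
mean-squared-error estimator).  Interval: the 95% highest density interval,
the shortest interval holding the stated posterior mass; both always lie in
[0, 1], so the truncation problem of the Rogan-Gladen estimator cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "gibbs_sample",
    "gibbs_batch",
    "psrf",
    "hdi",
    "effective_sample_size",
    "summarize",
]


@dataclass(frozen=True)
class PriorSpec:
    """Beta prior shape pairs for (pi, Se, Sp)."""

    pi_prior: tuple[float, float] = (1.0, 1.0)
    se_prior: tuple[float, float] = (1.0, 1.0)
    sp_prior: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        for pair in (self.pi_prior, self.se_prior, self.sp_prior):
            if min(pair) <= 0:
                raise ValueError("Beta shapes must be positive")

    @classmethod
    def from_validation(cls, x_se: int, n_se: int, x_sp: int, n_sp: int,
                        pi_prior: tuple[float, float] = (1.0, 1.0)) -> "PriorSpec":
        """Validation-informed priors: Beta(1,1) updated with the study counts."""
        return cls(
            pi_prior=pi_prior,
            se_prior=(x_se + 1.0, n_se - x_se + 1.0),
            sp_prior=(x_sp + 1.0, n_sp - x_sp + 1.0),
        )


@dataclass(frozen=True)
class McmcConfig:
    """Sampler run lengths and convergence policy.

    Defaults mirror the validation study: 3 chains, 5,000 discarded
    iterations per chain (4,000 burn-in plus the 1,000 warm-up iterations the
    original JAGS runs spent adapting, which a Gibbs sampler does not need but
    we keep discarding for comparability), and ~20,000 retained draws pooled
    across chains.
    """

    n_chains: int = 3
    n_burnin: int = 5000
    n_samples: int = 6667  # per chain; 3 chains -> ~20,000 pooled
    seed: int = 0
    psrf_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_samples < 1 or self.n_burnin < 0:
            raise ValueError("invalid MCMC configuration")


@dataclass
class PosteriorDraws:
    """Per-chain posterior draws; arrays of shape (n_chains, n_samples)."""

    pi: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    extended: bool = False

    @property
    def n_chains(self) -> int:
        return self.pi.shape[0]

    @property
    def pooled_pi(self) -> np.ndarray:
        return self.pi.reshape(-1)


@dataclass(frozen=True)
class PosteriorSummary:
    mean_pi: float
    hdi_low: float
    hdi_high: float
    psrf_pi: float
    ess_pi: float
    converged: bool


# ---------------------------------------------------------------------------
# core vectorised sampler
# ---------------------------------------------------------------------------

_INIT_PI = np.array([0.1, 0.5, 0.9, 0.25, 0.75])  # cycled over chains


def _run_chains(x, n, a_pi, b_pi, a_se, b_se, a_sp, b_sp, cfg: McmcConfig,
                rng: np.random.Generator, n_samples: int, keep=("pi",)):
    """Run the Gibbs recursion for a batch of datasets.

    All count/shape inputs are 1-d arrays of length m (one entry per
    dataset).  State arrays have shape (n_chains, m).  Returns a dict of
    retained draws with shape (n_chains, m, n_samples), float32.
    """
    x = np.asarray(x, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    m = x.shape[0]
    C = cfg.n_chains

    pi = np.tile(_INIT_PI[np.arange(C) % len(_INIT_PI)][:, None], (1, m))
    se = np.broadcast_to(a_se / (a_se + b_se), (C, m)).copy()
    sp = np.broadcast_to(a_sp / (a_sp + b_sp), (C, m)).copy()
    np.clip(se, 1e-6, 1 - 1e-6, out=se)
    np.clip(sp, 1e-6, 1 - 1e-6, out=sp)

    n_minus_x = n - x
    out = {k: np.empty((C, m, n_samples), dtype=np.float32) for k in keep}
    state = {"pi": pi, "se": se, "sp": sp}

    total = cfg.n_burnin + n_samples
    for it in range(total):
        pos = pi * se
        neg = pi * (1.0 - se)
        p1 = pos / (pos + (1.0 - pi) * (1.0 - sp))
        p2 = neg / (neg + (1.0 - pi) * sp)
        t1 = rng.binomial(x, p1)
        t2 = rng.binomial(n_minus_x, p2)
        d = t1 + t2
        pi = rng.beta(a_pi + d, b_pi + (n - d))
        se = rng.beta(a_se + t1, b_se + t2)
        sp = rng.beta(a_sp + (n_minus_x - t2), b_sp + (x - t1))
        if it >= cfg.n_burnin:
            j = it - cfg.n_burnin
            state = {"pi": pi, "se": se, "sp": sp}
            for k in keep:
                out[k][:, :, j] = state[k]
    return out


def _psrf_from_array(draws: np.ndarray) -> np.ndarray:
    """PSRF along the last axis; draws shaped (n_chains, ..., n_samples)."""
    S = draws.shape[-1]
    chain_mean = draws.mean(axis=-1, dtype=np.float64)
    chain_var = draws.var(axis=-1, ddof=1, dtype=np.float64)
    W = chain_var.mean(axis=0)
    B_over_S = chain_mean.var(axis=0, ddof=1, dtype=np.float64)
    var_plus = (S - 1) / S * W + B_over_S
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / W)
    return np.where(W > 0, out, 1.0)


def _hdi_sorted_2d(sorted_draws: np.ndarray, mass: float):
    """HDI from row-sorted draws (m, N): shortest window holding ceil(mass*N)."""
    m, N = sorted_draws.shape
    w = int(np.ceil(mass * N))
    if w >= N:
        return sorted_draws[:, 0].astype(float), sorted_draws[:, -1].astype(float)
    widths = sorted_draws[:, w - 1:] - sorted_draws[:, : N - w + 1]
    i = np.argmin(widths, axis=1)  # ties -> lowest start index
    rows = np.arange(m)
    return (sorted_draws[rows, i].astype(float),
            sorted_draws[rows, i + w - 1].astype(float))


def _ess_from_chains(draws: np.ndarray, max_chunk: int = 256) -> np.ndarray:
    """Autocorrelation-sum ESS; draws shaped (n_chains, m, n_samples).

    Chain autocorrelations are averaged, summed until they drop below 0.05
    (or turn negative); ESS = pooled draws / (1 + 2 * sum).  Reporting-grade
    only, not used for gating.
    """
    C, m, S = draws.shape
    nfft = 1 << int(np.ceil(np.log2(2 * S)))
    ess = np.empty(m)
    for lo in range(0, m, max_chunk):
        hi = min(lo + max_chunk, m)
        block = draws[:, lo:hi, :].astype(np.float64)
        block = block - block.mean(axis=-1, keepdims=True)
        f = np.fft.rfft(block, nfft, axis=-1)
        acov = np.fft.irfft(f * np.conj(f), nfft, axis=-1)[..., :S]
        acov /= np.arange(S, 0, -1)  # unbiased normalisation
        rho = (acov / np.where(acov[..., :1] > 0, acov[..., :1], 1.0)).mean(axis=0)
        valid = np.cumprod(rho[:, 1:] >= 0.05, axis=1)
        tau = 1.0 + 2.0 * np.sum(rho[:, 1:] * valid, axis=1)
        ess[lo:hi] = np.minimum(C * S / np.maximum(tau, 1.0), C * S)
    return ess


def gibbs_batch(data: pd.DataFrame, cfg: McmcConfig, *,
                pi_prior: tuple[float, float] = (1.0, 1.0),
                compute_ess: bool = True,
                batch_size: int = 4000) -> pd.DataFrame:
    """Fit the Bayesian model to every dataset of a table, vectorised.

    ``data`` needs columns x, n, x_se, n_se, x_sp, n_sp (one row per
    dataset).  Returns a DataFrame aligned with ``data``'s rows with columns
    point (posterior mean of pi), lower / upper (95% HDI), psrf, ess,
    converged.  Datasets whose PSRF misses the threshold are re-run once with
    doubled retained length.
    """
    cols = ["x", "n", "x_se", "n_se", "x_sp", "n_sp"]
    arr = {c: data[c].to_numpy() for c in cols}
    m = len(data)
    out = {
        "point": np.empty(m), "lower": np.empty(m), "upper": np.empty(m),
        "psrf": np.empty(m), "ess": np.full(m, np.nan), "converged": np.zeros(m, dtype=bool),
    }
    for lo in range(0, m, batch_size):
        hi = min(lo + batch_size, m)
        sl = {c: arr[c][lo:hi] for c in cols}
        rng = np.random.default_rng(np.random.SeedSequence((int(cfg.seed), 0, 0, lo)))
        _fit_block(sl, cfg, pi_prior, rng, out, lo, hi, compute_ess)
    return pd.DataFrame(out, index=data.index)


def _fit_block(sl, cfg, pi_prior, rng, out, lo, hi, compute_ess) -> None:
    a_pi, b_pi = pi_prior
    a_se = sl["x_se"] + 1.0
    b_se = sl["n_se"] - sl["x_se"] + 1.0
    a_sp = sl["x_sp"] + 1.0
    b_sp = sl["n_sp"] - sl["x_sp"] + 1.0

    def run(idx: np.ndarray, n_samples: int):
        draws = _run_chains(
            sl["x"][idx], sl["n"][idx], a_pi, b_pi,
            a_se[idx], b_se[idx], a_sp[idx], b_sp[idx],
            cfg, rng, n_samples,
        )["pi"]
        return draws

    all_idx = np.arange(hi - lo)
    draws = run(all_idx, cfg.n_samples)
    r = _psrf_from_array(draws)
    bad = r >= cfg.psrf_threshold
    if np.any(bad):
        redraws = run(all_idx[bad], 2 * cfg.n_samples)
        r2 = _psrf_from_array(redraws)
        r[bad] = r2
        pooled_bad = redraws.transpose(1, 0, 2).reshape(int(bad.sum()), -1)
        _store(out, lo + all_idx[bad], pooled_bad, r2, cfg,
               _ess_from_chains(redraws) if compute_ess else None)
    good = ~bad
    pooled = draws[:, good, :].transpose(1, 0, 2).reshape(int(good.sum()), -1)
    _store(out, lo + all_idx[good], pooled, r[good], cfg,
           _ess_from_chains(draws[:, good, :]) if compute_ess else None)


def _store(out, pos, pooled, r, cfg, ess) -> None:
    if len(pos) == 0:
        return
    out["point"][pos] = pooled.mean(axis=1, dtype=np.float64)
    s = np.sort(pooled, axis=1)
    lo_, hi_ = _hdi_sorted_2d(s, 0.95)
    out["lower"][pos] = lo_
    out["upper"][pos] = hi_
    out["psrf"][pos] = r
    out["converged"][pos] = r < cfg.psrf_threshold
    if ess is not None:
        out["ess"][pos] = ess


# ---------------------------------------------------------------------------
# single-dataset interface
# ---------------------------------------------------------------------------

def gibbs_sample(c, sizes, prior: PriorSpec | None = None,
                 cfg: McmcConfig = McmcConfig()) -> PosteriorDraws:
    """Sample the joint posterior of (pi, Se, Sp) for one dataset.

    ``c`` carries counts x / x_se / x_sp; ``sizes`` is (n, n_se, n_sp).
    When ``prior`` is None the validation-informed default is built from the
    dataset's own validation counts.
    """
    n, n_se, n_sp = (int(s) for s in sizes)
    x = int(c.x)
    if not 0 <= x <= n:
        raise ValueError("x out of range")
    if prior is None:
        prior = PriorSpec.from_validation(int(c.x_se), n_se, int(c.x_sp), n_sp)
    rng = np.random.default_rng(np.random.SeedSequence((int(cfg.seed), 0, 0, 2**30)))

    def run(n_samples: int) -> PosteriorDraws:
        draws = _run_chains(
            np.array([x]), np.array([n]),
            prior.pi_prior[0], prior.pi_prior[1],
            np.array([prior.se_prior[0]]), np.array([prior.se_prior[1]]),
            np.array([prior.sp_prior[0]]), np.array([prior.sp_prior[1]]),
            cfg, rng, n_samples, keep=("pi", "se", "sp"),
        )
        return PosteriorDraws(
            pi=draws["pi"][:, 0, :].astype(np.float64),
            se=draws["se"][:, 0, :].astype(np.float64),
            sp=draws["sp"][:, 0, :].astype(np.float64),
        )

    d = run(cfg.n_samples)
    if cfg.n_chains >= 2 and psrf(d) >= cfg.psrf_threshold:
        d = run(2 * cfg.n_samples)
        d.extended = True
    return d


def psrf(draws) -> float:
    """Gelman-Rubin potential scale reduction factor for the prevalence.

    Accepts a :class:`PosteriorDraws` or a (n_chains, n_samples) array;
    requires at least two chains.
    """
    arr = draws.pi if isinstance(draws, PosteriorDraws) else np.asarray(draws, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("psrf requires >= 2 chains of draws")
    return float(_psrf_from_array(arr))


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Highest density interval: the shortest window over the sorted draws
    containing ceil(mass * N) of them.  Ties broken by the lowest start."""
    s = np.sort(np.asarray(samples, dtype=float).reshape(-1))
    if s.size == 0:
        raise ValueError("hdi requires a non-empty sample")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    lo, hi = _hdi_sorted_2d(s[None, :], mass)
    return float(lo[0]), float(hi[0])


def effective_sample_size(draws) -> float:
    """Autocorrelation-sum effective sample size of the pooled pi draws."""
    arr = draws.pi if isinstance(draws, PosteriorDraws) else np.asarray(draws, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return float(_ess_from_chains(arr[:, None, :])[0])


def summarize(draws: PosteriorDraws, cfg: McmcConfig = McmcConfig()) -> PosteriorSummary:
    """Posterior mean, 95% HDI, PSRF and ESS of the prevalence."""
    pooled = draws.pooled_pi
    mean = float(pooled.mean())
    lo, hi = hdi(pooled, 0.95)
    r = psrf(draws) if draws.n_chains >= 2 else float("nan")
    ess = effective_sample_size(draws)
    converged = bool(r < cfg.psrf_threshold) if np.isfinite(r) else True
    return PosteriorSummary(mean, lo, hi, r, ess, converged)
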