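"""Simulation of replicate count datasets and their maximum-likelihood estimates.

For each scenario, replicate datasets are drawn independently as

    x_se ~ Binomial(n_se, Se),   x_sp ~ Binomial(n_sp, Sp),
    x    ~ Binomial(n, AP),      AP = Se*pi + (1-Sp)*(1-pi),

mimicking a sensitivity validation study, a specificity validation study and
one application of the test.  The MLEs are the plain count ratios.

Datasets whose estimated test does not discriminate better than chance
(1 - sp_hat >= se_hat) are labelled ``excluded``: such a test would not be
used in practice and the misclassification adjustment is undefined or
inverted for it.  Retained datasets are classified by where the raw
(non-truncated) Rogan-Gladen estimate falls: ``case1`` within [0, 1],
``case2`` below 0, ``case3`` above 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenarios import TrueParameters, scenario_rng, true_apparent_prevalence

__all__ = [
    "CountData",
    "MLEstimates",
    "draw_counts",
    "simulate_datasets",
    "mle",
    "classify",
    "classify_arrays",
]

DATA_COLUMNS = [
    "scenario_id",
    "replicate_id",
    "x_se",
    "x_sp",
    "x",
    "se_hat",
    "sp_hat",
    "ap_hat",
    "case",
]


@dataclass(frozen=True)
class CountData:
    """One replicate dataset of counts."""

    scenario_id: int
    replicate_id: int
    x_se: int
    x_sp: int
    x: int


@dataclass(frozen=True)
class MLEstimates:
    """Maximum-likelihood proportions for one dataset."""

    se_hat: float
    sp_hat: float
    ap_hat: float


def draw_counts(p: TrueParameters, n_replicates: int, seed: int) -> pd.DataFrame:
    """Draw ``n_replicates`` count datasets for one scenario.

    The scenario's substream is derived from ``(seed, scenario_id)`` only, so
    the replicates do not depend on which other scenarios were simulated.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = scenario_rng(seed, p.scenario_id)
    ap = true_apparent_prevalence(p.se_true, p.sp_true, p.pi_true)
    df = pd.DataFrame(
        {
            "scenario_id": p.scenario_id,
            "replicate_id": np.arange(1, n_replicates + 1),
            "x_se": rng.binomial(p.n_se, p.se_true, n_replicates),
            "x_sp": rng.binomial(p.n_sp, p.sp_true, n_replicates),
            "x": rng.binomial(p.n, ap, n_replicates),
        }
    )
    return df


def mle(c: CountData | pd.DataFrame, p: TrueParameters | None = None, *, sizes=None):
    """Maximum-likelihood proportions se_hat, sp_hat, ap_hat (exact ratios)."""
    if isinstance(c, CountData):
        if p is None and sizes is None:
            raise ValueError("scenario sizes required")
        n_se, n_sp, n = (p.n_se, p.n_sp, p.n) if p is not None else sizes
        for count, size, name in ((c.x_se, n_se, "x_se"), (c.x_sp, n_sp, "x_sp"), (c.x, n, "x")):
            if not 0 <= count <= size:
                raise ValueError(f"{name} out of range")
        return MLEstimates(c.x_se / n_se, c.x_sp / n_sp, c.x / n)
    raise TypeError("mle expects a CountData; use simulate_datasets for tables")


def classify(m: MLEstimates) -> str:
    """Classify a dataset by its MLEs: excluded / case1 / case2 / case3.

    ``excluded`` iff 1 - sp_hat >= se_hat (strict condition Se_hat + Sp_hat > 1
    fails); otherwise case2 iff the raw Rogan-Gladen estimate is negative
    (ap_hat < 1 - sp_hat), case3 iff it exceeds one (ap_hat > se_hat), and
    case1 otherwise.  Boundary values (raw estimate exactly 0 or 1) are case1.
    """
    return str(classify_arrays(m.se_hat, m.sp_hat, m.ap_hat))


def classify_arrays(se_hat, sp_hat, ap_hat):
    """Vectorised dataset classification; returns str or array of str."""
    se_hat = np.asarray(se_hat, dtype=float)
    sp_hat = np.asarray(sp_hat, dtype=float)
    ap_hat = np.asarray(ap_hat, dtype=float)
    out = np.full(np.broadcast(se_hat, sp_hat, ap_hat).shape, "case1", dtype=object)
    fn = 1.0 - sp_hat  # false-positive probability estimate
    out[np.broadcast_to(ap_hat < fn, out.shape)] = "case2"
    out[np.broadcast_to(ap_hat > se_hat, out.shape)] = "case3"
    out[np.broadcast_to(fn >= se_hat, out.shape)] = "excluded"
    if out.ndim == 0:
        return out[()]
    return out


def simulate_datasets(scenarios: pd.DataFrame, n_replicates: int, seed: int) -> pd.DataFrame:
    """Simulate ``n_replicates`` datasets per scenario with MLEs and case labels.

    Iterates scenarios (each with its own substream) but draws the replicate
    block for a scenario as vectors, so the full 1,000 x 1,000 design runs in
    seconds.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    frames = []
    rep_ids = np.arange(1, n_replicates + 1)
    for row in scenarios.itertuples(index=False):
        rng = scenario_rng(seed, row.scenario_id)
        ap = true_apparent_prevalence(row.se_true, row.sp_true, row.pi_true)
        x_se = rng.binomial(row.n_se, row.se_true, n_replicates)
        x_sp = rng.binomial(row.n_sp, row.sp_true, n_replicates)
        x = rng.binomial(row.n, ap, n_replicates)
        se_hat = x_se / row.n_se
        sp_hat = x_sp / row.n_sp
        ap_hat = x / row.n
        frames.append(
            pd.DataFrame(
                {
                    "scenario_id": np.full(n_replicates, row.scenario_id),
                    "replicate_id": rep_ids,
                    "x_se": x_se,
                    "x_sp": x_sp,
                    "x": x,
                    "se_hat": se_hat,
                    "sp_hat": sp_hat,
                    "ap_hat": ap_hat,
                    "case": classify_arrays(se_hat, sp_hat, ap_hat),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_data_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=DATA_COLUMNS)


def read_data_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(DATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"data table missing columns: {sorted(missing)}")
    return df
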