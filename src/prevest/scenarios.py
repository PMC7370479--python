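"""Simulation of true parameter sets for the validation study.

Each scenario ("parameter set") consists of three statistical parameters --
true prevalence pi, true diagnostic sensitivity Se and specificity Sp -- and
three design parameters: the size ``n`` of the sample the test is applied to
and the sizes ``n_se`` / ``n_sp`` of the validation studies that estimated
Se and Sp against a gold standard.

Statistical parameters are drawn from continuous uniforms (Se, Sp from
U(0.6, 1); pi from U(0, 1)); the validation sizes from a fixed set of seven
common study sizes; ``n`` uniformly from the integers 50..2000.  Because the
true Se and Sp both exceed 0.6, every scenario's truth discriminates better
than chance (Se + Sp > 1), so the misclassification adjustment is always
well defined at the true values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VALIDATION_SIZES",
    "TrueParameters",
    "draw_scenarios",
    "true_apparent_prevalence",
    "scenario_rng",
]

#: Sample sizes available for the Se / Sp validation studies.
VALIDATION_SIZES = (50, 100, 200, 500, 1000, 2000, 5000)

#: Range (inclusive) of the test-application sample size n.
N_APPLICATION_RANGE = (50, 2000)

SCENARIO_COLUMNS = ["scenario_id", "se_true", "sp_true", "pi_true", "n_se", "n_sp", "n"]


@dataclass(frozen=True)
class TrueParameters:
    """One simulated truth: statistical and design parameters of a scenario."""

    scenario_id: int
    se_true: float
    sp_true: float
    pi_true: float
    n_se: int
    n_sp: int
    n: int

    def __post_init__(self) -> None:
        if not (0.6 < self.se_true < 1 and 0.6 < self.sp_true < 1):
            raise ValueError("se_true and sp_true must lie in (0.6, 1)")
        if not 0 < self.pi_true < 1:
            raise ValueError("pi_true must lie in (0, 1)")
        for name in ("n_se", "n_sp", "n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def apparent_prevalence(self) -> float:
        return true_apparent_prevalence(self.se_true, self.sp_true, self.pi_true)


def scenario_rng(seed: int, scenario_id: int, stage: int = 1) -> np.random.Generator:
    """Deterministic per-scenario random substream.

    Scenario ``k`` gets the same stream no matter how many scenarios are
    simulated, so any scenario (and its data) can be regenerated in
    isolation.  ``stage`` 0 is the parameter draw, 1 the count draw.
    """
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), int(scenario_id), int(stage)))
    )


def draw_scenarios(n_scenarios: int, seed: int) -> pd.DataFrame:
    """Draw ``n_scenarios`` independent true parameter sets.

    Returns a DataFrame with columns scenario_id, se_true, sp_true, pi_true,
    n_se, n_sp, n; scenario_id runs 1..n_scenarios in generation order.
    Each scenario is drawn from its own substream, so row ``k`` does not
    depend on ``n_scenarios``.
    """
    if n_scenarios < 1:
        raise ValueError("n_scenarios must be >= 1")
    sizes = np.asarray(VALIDATION_SIZES)
    lo, hi = N_APPLICATION_RANGE
    rows = np.empty((n_scenarios, 6))
    for i in range(n_scenarios):
        rng = scenario_rng(seed, i + 1, stage=0)
        rows[i, :3] = (rng.uniform(0.6, 1.0), rng.uniform(0.6, 1.0), rng.uniform(0.0, 1.0))
        rows[i, 3] = rng.choice(sizes)
        rows[i, 4] = rng.choice(sizes)
        rows[i, 5] = rng.integers(lo, hi + 1)
    df = pd.DataFrame(
        {
            "scenario_id": np.arange(1, n_scenarios + 1),
            "se_true": rows[:, 0],
            "sp_true": rows[:, 1],
            "pi_true": rows[:, 2],
            "n_se": rows[:, 3].astype(np.int64),
            "n_sp": rows[:, 4].astype(np.int64),
            "n": rows[:, 5].astype(np.int64),
        }
    )
    return df


def true_apparent_prevalence(se, sp, pi):
    """Probability of a positive test result: AP = Se*pi + (1-Sp)*(1-pi).

    Accepts scalars or arrays (broadcast).  Also accepts a single
    :class:`TrueParameters` as the only argument via :func:`ap_of`.
    """
    se = np.asarray(se, dtype=float)
    sp = np.asarray(sp, dtype=float)
    pi = np.asarray(pi, dtype=float)
    out = se * pi + (1.0 - sp) * (1.0 - pi)
    if out.ndim == 0:
        return float(out)
    return out


def ap_of(p: TrueParameters) -> float:
    """Apparent prevalence of a scenario's truth."""
    return true_apparent_prevalence(p.se_true, p.sp_true, p.pi_true)


def write_scenarios_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=SCENARIO_COLUMNS)


def read_scenarios_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SCENARIO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scenario table missing columns: {sorted(missing)}")
    return df
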