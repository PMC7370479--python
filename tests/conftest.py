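import numpy as np
import pandas as pd
import pytest

from prevest.datasim import CountData
from prevest.scenarios import TrueParameters

# first parameter set of the worked example: a moderately accurate test
# (Se=0.748, Sp=0.933) applied to 323 individuals, validated on 100/200
WORKED_SCENARIO = TrueParameters(
    scenario_id=1, se_true=0.7479478, sp_true=0.9332674, pi_true=0.4459405,
    n_se=100, n_sp=200, n=323,
)

# replicate datasets drawn from that scenario: (x_se, x_sp, x, se_hat, sp_hat, ap_hat)
WORKED_DATASETS = [
    (74, 193, 129, 0.74, 0.965, 0.3993808),
    (70, 189, 125, 0.70, 0.945, 0.3869969),
    (78, 189, 124, 0.78, 0.945, 0.3839009),
    (73, 191, 109, 0.73, 0.955, 0.3374613),
    (76, 184, 117, 0.76, 0.920, 0.3622291),
]


@pytest.fixture(scope="session")
def worked_scenario():
    return WORKED_SCENARIO


@pytest.fixture(scope="session")
def worked_counts():
    return CountData(scenario_id=1, replicate_id=1, x_se=74, x_sp=193, x=129)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study shared across validation-layer tests."""
    import prevest

    scen = prevest.draw_scenarios(30, seed=123)
    data = prevest.simulate_datasets(scen, 40, seed=123)
    return scen, data
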