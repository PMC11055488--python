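import numpy as np
import pandas as pd
import pytest

from effortbench.simulate import CohortConfig, make_cohort, simulate_experiment


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(n_participants=18, seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    return make_cohort(default_config)


@pytest.fixture(scope="session")
def large_simulation():
    """A few hundred participants, full test-retest design; shared across tests."""
    cfg = CohortConfig(n_participants=250, seed=20)
    svt, swirt, cohort = simulate_experiment(cfg)
    return svt, swirt, cohort


def make_binomial_mixed(n_groups, per_group, beta, sd, seed, x=None):
    """Simulate y ~ x + (1|g) binomial data with known truth (test oracle)."""
    rng = np.random.default_rng(seed)
    n = n_groups * per_group
    x = rng.normal(size=n) if x is None else x
    g = np.repeat(np.arange(n_groups), per_group)
    b = rng.normal(0.0, sd, n_groups)
    eta = beta[0] + beta[1] * x + b[g]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return pd.DataFrame({"y": y, "x": x, "g": g})
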