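"""Shared fixtures: small seeded datasets used across the test modules."""

import numpy as np
import pandas as pd
import pytest

from einvpolicy import MultiEnvDataset, simulate_example1, simulate_intro

#: Hand-picked Example 1 parameter sets (gamma1, gamma2, gamma3, mu).
#: gamma1 differs strongly across environments (E[U1 | x1] slope
#: gamma1/(1+gamma1^2): 0.2 vs -0.4), so {x1} and {x3} are clearly not
#: e-invariant while {x2} is.
EX1_PARAMS = [(0.5, 1.0, 0.5, 1.0), (-2.0, -2.0, -1.5, 0.0)]


@pytest.fixture(scope="session")
def ex1_linear():
    return simulate_example1(EX1_PARAMS, 1000, variant="linear", seed=42)


@pytest.fixture(scope="session")
def ex1_nonlinear_main():
    return simulate_example1(EX1_PARAMS, 1000, variant="nonlinear_main", seed=43)


@pytest.fixture(scope="session")
def intro_sim():
    return simulate_intro([1.0, -1.0], 1000, seed=7)


@pytest.fixture()
def tiny_dataset():
    """Balanced two-environment toy log with Bernoulli(0.5) randomization."""
    rng = np.random.default_rng(3)
    n = 600
    x = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
    t = rng.integers(0, 2, n)
    env = np.repeat([0, 1], n // 2)
    y = 1.0 + x["a"].to_numpy() + t * (0.5 + x["b"].to_numpy()) \
        + rng.standard_normal(n)
    prop = np.full(n, 0.5)
    return MultiEnvDataset(y=y, x=x, t=t, env=env, prop=prop)
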