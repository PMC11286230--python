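"""Unit tests for the linear-CATE Wald e-invariance test."""

import numpy as np
import pandas as pd
import pytest

from einvpolicy import (ConfigError, DegenerateDesignError, MultiEnvDataset,
                        Policy, PositivityError, UnsupportedTreatmentError,
                        compute_weights, fit_gmm, make_bernoulli_policy,
                        simulate_example1, wald_einv_test)
from einvpolicy.wald_test import center_treatment
from tests.conftest import EX1_PARAMS


def test_center_treatment_values():
    pol = make_bernoulli_policy(0.3)
    assert center_treatment(1, {"x": 0.0}, pol) == pytest.approx(0.7)
    assert center_treatment(0, {"x": 0.0}, pol) == pytest.approx(-0.3)


def test_weights_are_policy_ratio(tiny_dataset):
    pol = make_bernoulli_policy(0.5)
    w = compute_weights(tiny_dataset, (), pol)
    np.testing.assert_allclose(w, np.ones(tiny_dataset.n))
    pol2 = make_bernoulli_policy(0.25)
    w2 = compute_weights(tiny_dataset, (), pol2)
    want = np.where(tiny_dataset.t == 1, 0.25, 0.75) / 0.5
    np.testing.assert_allclose(w2, want)


def test_centering_policy_must_live_on_subset(tiny_dataset):
    outside = Policy(lambda x: np.tile([0.5, 0.5], (len(x), 1)), k=2,
                     support_subset=("b",))
    with pytest.raises(ConfigError):
        compute_weights(tiny_dataset, ("a",), outside)
    undeclared = Policy(lambda x: np.tile([0.5, 0.5], (len(x), 1)), k=2,
                        support_subset=None)
    with pytest.raises(ConfigError):
        compute_weights(tiny_dataset, ("a",), undeclared)


def test_fit_gmm_shapes_and_df(ex1_linear):
    fit = fit_gmm(ex1_linear.data, ("x2",))
    d, s = 3, 1
    assert fit.alpha_hat.shape == (1 + d,)
    assert fit.A_hat.shape == (1, 1 + d)
    assert fit.beta_hat.shape == (1 + s,)
    assert fit.B_hat.shape == (1, 1 + s)
    assert fit.q_dim == (2 - 1) * (1 + s)
    assert fit.V_hat.shape == (fit.q_dim, fit.q_dim)


def test_fit_gmm_rank_deficiency_names_columns():
    rng = np.random.default_rng(0)
    n = 100
    a = rng.standard_normal(n)
    x = pd.DataFrame({"a": a, "b": a})  # duplicated column
    data = MultiEnvDataset(y=rng.standard_normal(n), x=x,
                           t=rng.integers(0, 2, n),
                           env=np.repeat([0, 1], n // 2),
                           prop=np.full(n, 0.5))
    with pytest.raises(DegenerateDesignError, match="rank deficient"):
        fit_gmm(data, ("a",))


def test_wald_rejects_multilevel_treatment():
    x = pd.DataFrame({"a": np.linspace(-1, 1, 12)})
    data = MultiEnvDataset(y=np.zeros(12), x=x, t=[0, 1, 2] * 4,
                           env=[0] * 6 + [1] * 6, prop=np.full(12, 1 / 3))
    with pytest.raises(UnsupportedTreatmentError):
        wald_einv_test(data, ("a",))


def test_wald_needs_two_environments(tiny_dataset):
    one_env = tiny_dataset.subset_rows(
        np.flatnonzero(tiny_dataset.env == 0))
    with pytest.raises(ConfigError):
        wald_einv_test(one_env, ("a",))


def test_wald_estimated_propensity_warning(ex1_linear):
    with pytest.warns(UserWarning, match="estimated"):
        wald_einv_test(ex1_linear.data, ("x2",), propensities_estimated=True)


def test_wald_detects_clear_non_invariance():
    # {x1} is strongly non-e-invariant under EX1_PARAMS at n=8000
    sim = simulate_example1(EX1_PARAMS, 4000, variant="linear", seed=10)
    res = wald_einv_test(sim.data, ("x1",))
    assert res.reject
    assert res.method == "wald"
    assert res.df == 2


def test_wald_consistency_of_invariant_coefficients():
    # Neyman orthogonality: beta_hat for S={x2} recovers (1, 0.5) under the
    # nonlinear (misspecified) main effect at large n
    sim = simulate_example1(EX1_PARAMS, 50000, variant="nonlinear_main",
                            seed=11)
    fit = fit_gmm(sim.data, ("x2",))
    assert fit.beta_hat[0] == pytest.approx(1.0, abs=0.2)
    assert fit.beta_hat[1] == pytest.approx(0.5, abs=0.2)
    # interaction coefficients vanish for the e-invariant subset, up to the
    # fit's own sampling noise (the policy-ratio weights are heavy tailed)
    se = np.sqrt(np.diag(fit.V_hat) / fit.n)
    assert np.all(np.abs(fit.B_hat.ravel()) < 4.0 * se)


def test_wald_statistic_invariant_to_env_relabeling(ex1_linear):
    data = ex1_linear.data
    relabeled = MultiEnvDataset(y=data.y, x=data.x, t=data.t,
                                env=np.where(data.env == 0, 10, 20),
                                prop=data.prop)
    a = wald_einv_test(data, ("x2",))
    b = wald_einv_test(relabeled, ("x2",))
    assert a.statistic == pytest.approx(b.statistic, rel=1e-9)
    assert a.p_value == pytest.approx(b.p_value, rel=1e-9)


def test_wald_positivity_guard(tiny_dataset):
    bad = MultiEnvDataset.__new__(MultiEnvDataset)
    bad.y, bad.x, bad.t = tiny_dataset.y, tiny_dataset.x, tiny_dataset.t
    bad.env = tiny_dataset.env
    bad.prop = tiny_dataset.prop.copy()
    bad.prop[0] = 0.0  # bypass constructor validation on purpose
    with pytest.raises(PositivityError):
        compute_weights(bad, (), make_bernoulli_policy(0.5))
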