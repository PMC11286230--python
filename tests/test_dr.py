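"""Unit tests for the nonparametric DR-learner e-invariance test."""

import numpy as np
import pandas as pd
import pytest

from einvpolicy import (ConfigError, DRTestConfig, dr_einv_test,
                        direction_weights, fit_nuisances,
                        gcm_mean_equality_test, simulate_example1,
                        split_sample)
from einvpolicy import MultiEnvDataset
from tests.conftest import EX1_PARAMS


def test_split_sample_disjoint_exhaustive_stratified(ex1_linear):
    d1, d2 = split_sample(ex1_linear.data, 0.5, seed=3)
    assert d1.n + d2.n == ex1_linear.data.n
    # every env x arm stratum is represented on both halves
    for half in (d1, d2):
        for e in half.environments:
            m = half.env == e
            assert half.t[m].min() == 0 and half.t[m].max() == 1
    # deterministic given the seed
    d1b, _ = split_sample(ex1_linear.data, 0.5, seed=3)
    np.testing.assert_allclose(d1.y, d1b.y)


def test_fit_nuisances_known_propensities(ex1_linear):
    d1, d2 = split_sample(ex1_linear.data, 0.5, seed=0)
    nuis = fit_nuisances(d1, "linear", known_propensities=True)
    np.testing.assert_allclose(nuis.pi_treat(d2), d2.propensity_of_treat())
    # per-environment mu_e(x, t) callables
    assert set(nuis.mu_bar) == set(d1.environments)
    grid = d2.x.iloc[:3]
    for mu in nuis.mu_bar.values():
        assert mu(grid, 1).shape == (3,)
        assert mu(grid, 0).shape == (3,)


def test_fit_nuisances_estimated_propensities_bounded(ex1_linear):
    d1, d2 = split_sample(ex1_linear.data, 0.5, seed=0)
    nuis = fit_nuisances(d1, "linear", known_propensities=False)
    p = nuis.pi_treat(d2)
    assert np.all(p >= 1e-3) and np.all(p <= 1 - 1e-3)


def test_gcm_zero_residuals_gives_zero_statistic():
    # constant o conditioned on the empty subset has exactly zero residuals
    n = 200
    o = np.full(n, 2.5)
    xs = np.empty((n, 0))
    env = np.repeat([0, 1], n // 2)
    stat, df, p = gcm_mean_equality_test(o, xs, env, seed=0)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert df == 1
    assert p == pytest.approx(1.0)


def test_gcm_needs_two_environments():
    with pytest.raises(ConfigError):
        gcm_mean_equality_test(np.zeros(10), np.zeros((10, 1)),
                               np.zeros(10, dtype=int))


def test_gcm_level_under_independent_env_labels():
    # env labels independent of (o, x_S): rejection near nominal
    rng = np.random.default_rng(12)
    reps, n, alpha = 200, 500, 0.05
    rej = 0
    for r in range(reps):
        xs = rng.standard_normal((n, 1))
        o = 1.0 + 0.5 * xs[:, 0] + rng.standard_normal(n)
        env = rng.integers(0, 2, n)
        _, _, p = gcm_mean_equality_test(o, xs, env, seed=r)
        rej += p < alpha
    # 3 binomial SDs around 0.05 with 200 reps
    assert abs(rej / reps - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)


def test_gcm_detects_location_alternative():
    rng = np.random.default_rng(4)
    n = 2000
    xs = rng.standard_normal((n, 1))
    env = rng.integers(0, 2, n)
    o = 1.0 + 0.5 * xs[:, 0] + 0.8 * env + rng.standard_normal(n)
    _, _, p = gcm_mean_equality_test(o, xs, env, seed=0)
    assert p < 0.01


def test_gcm_weight_shape_validation():
    n = 100
    o = np.random.default_rng(0).standard_normal(n)
    xs = np.zeros((n, 1))
    env = np.repeat([0, 1], n // 2)
    with pytest.raises(ConfigError):
        gcm_mean_equality_test(o, xs, env, weights=np.ones(n - 1))


def test_direction_weights_are_signs_aligned_with_gap():
    rng = np.random.default_rng(8)
    n = 4000
    xs = rng.standard_normal((n, 1))
    env = rng.integers(0, 2, n)
    # gap E[o|xs,env=1] - E[o|xs,env=0] = xs (odd function)
    o = xs[:, 0] * env + 0.3 * rng.standard_normal(n)
    w = direction_weights(o, xs, env, seed=0)
    assert w.shape == (n, 1)
    assert set(np.unique(w)) <= {-1.0, 1.0}
    # out-of-fold sign should mostly agree with sign(xs)
    agree = np.mean(w[:, 0] == np.sign(xs[:, 0]))
    assert agree > 0.9


def test_direction_weight_restores_power_on_odd_gap():
    # odd gap, symmetric covariates: plain product mean cancels, weighted not
    rng = np.random.default_rng(21)
    n = 4000
    xs = rng.standard_normal((n, 1))
    env = rng.integers(0, 2, n)
    o = 0.5 * xs[:, 0] * env + rng.standard_normal(n)
    _, _, p_plain = gcm_mean_equality_test(o, xs, env, seed=0)
    w = direction_weights(o, xs, env, seed=0)
    _, _, p_w = gcm_mean_equality_test(o, xs, env, weights=w, seed=0)
    assert p_w < 0.01
    assert p_w < p_plain


def test_dr_einv_test_invariant_subset_not_rejected(ex1_nonlinear_main):
    res = dr_einv_test(ex1_nonlinear_main.data, ("x2",),
                       config=DRTestConfig(seed=5))
    assert res.method == "dr"
    assert res.df == 1
    assert not res.reject


def test_dr_einv_test_detects_non_invariance():
    # gamma1 = +/-1 maximizes the E[U1 | x1] slope gap (+0.5 vs -0.5) with
    # moderate logging propensities, a clear {x1} alternative
    strong = [(1.0, 0.3, 0.3, 0.0), (-1.0, -0.3, -0.3, 1.0)]
    sim = simulate_example1(strong, 8000, variant="nonlinear_main", seed=6)
    res = dr_einv_test(sim.data, ("x1",), config=DRTestConfig(seed=6))
    assert res.reject


def test_dr_einv_test_env_rename_invariance(ex1_nonlinear_main):
    data = ex1_nonlinear_main.data
    renamed = MultiEnvDataset(y=data.y, x=data.x, t=data.t,
                              env=np.where(data.env == 0, 10, 20),
                              prop=data.prop)
    a = dr_einv_test(data, ("x2",), config=DRTestConfig(seed=2))
    b = dr_einv_test(renamed, ("x2",), config=DRTestConfig(seed=2))
    assert a.statistic == pytest.approx(b.statistic, rel=1e-9)


def test_dr_einv_test_empty_subset(ex1_linear):
    # the empty subset tests equality of unconditional mean effects
    res = dr_einv_test(ex1_linear.data, (), config=DRTestConfig(seed=1))
    assert res.subset == ()
    assert 0.0 <= res.p_value <= 1.0


def test_dr_config_weights_fn_hook(ex1_linear):
    calls = []

    def wfn(d2):
        calls.append(d2.n)
        return np.ones(d2.n)

    dr_einv_test(ex1_linear.data, ("x2",),
                 config=DRTestConfig(seed=0, weights_fn=wfn))
    assert calls and calls[0] == pytest.approx(ex1_linear.data.n / 2, abs=2)


def test_pseudo_outcome_double_robustness_one_sided():
    # with KNOWN propensities and an arbitrary (wrong) outcome model, the
    # pseudo-outcome conditional mean still equals the true CATE
    rng = np.random.default_rng(30)
    n = 200000
    x = rng.standard_normal(n)
    pi = 1.0 / (1.0 + np.exp(-x))
    t = (rng.random(n) < pi).astype(int)
    y = x + t * (1.0 + 2.0 * x) + rng.standard_normal(n)
    mu1_wrong = 5.0 - x          # deliberately wrong
    mu0_wrong = np.full(n, -3.0)
    o = (mu1_wrong - mu0_wrong
         + np.where(t == 1, (y - mu1_wrong) / pi, 0.0)
         - np.where(t == 0, (y - mu0_wrong) / (1 - pi), 0.0))
    m = np.abs(x) < 0.5
    true_cate = 1.0 + 2.0 * x[m]
    assert np.mean(o[m] - true_cate) == pytest.approx(0.0, abs=0.1)
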