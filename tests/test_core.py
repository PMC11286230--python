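"""Unit tests for the shared domain types and DR pseudo-outcomes."""

import numpy as np
import pandas as pd
import pytest

from einvpolicy import (CATEFunction, ConfigError, MultiEnvDataset, Policy,
                        PositivityError, SubsetTestResult, TreatmentSpace,
                        UnsupportedTreatmentError, make_bernoulli_policy,
                        make_constant_policy, pooled_cate_fit, pseudo_outcome,
                        pseudo_outcomes)
from einvpolicy.core import argmax_policy_probs, stratified_split_indices


# ---------------------------------------------------------------------------
# TreatmentSpace / MultiEnvDataset
# ---------------------------------------------------------------------------

def test_treatment_space_validation():
    TreatmentSpace(k=3, t0=2)
    with pytest.raises(ConfigError):
        TreatmentSpace(k=1)
    with pytest.raises(ConfigError):
        TreatmentSpace(k=2, t0=2)


def test_dataset_rejects_nonpositive_prop():
    x = pd.DataFrame({"a": [0.0, 1.0]})
    with pytest.raises(PositivityError):
        MultiEnvDataset(y=[0.0, 1.0], x=x, t=[0, 1], env=[0, 1],
                        prop=[0.5, 0.0])


def test_dataset_rejects_missing_fields():
    x = pd.DataFrame({"a": [0.0, np.nan]})
    with pytest.raises(ConfigError):
        MultiEnvDataset(y=[0.0, 1.0], x=x, t=[0, 1], env=[0, 1],
                        prop=[0.5, 0.5])
    with pytest.raises(ConfigError):
        MultiEnvDataset(y=[np.nan, 1.0], x=pd.DataFrame({"a": [0.0, 1.0]}),
                        t=[0, 1], env=[0, 1], prop=[0.5, 0.5])


def test_dataset_length_mismatch():
    with pytest.raises(ConfigError):
        MultiEnvDataset(y=[0.0, 1.0], x=pd.DataFrame({"a": [0.0]}),
                        t=[0, 1], env=[0, 1], prop=[0.5, 0.5])


def test_frame_roundtrip(tiny_dataset):
    frame = tiny_dataset.to_frame()
    back = MultiEnvDataset.from_frame(frame)
    assert back.covariate_names == tiny_dataset.covariate_names
    np.testing.assert_allclose(back.y, tiny_dataset.y)
    np.testing.assert_allclose(back.prop, tiny_dataset.prop)


def test_environments_sorted_and_subset_rows(tiny_dataset):
    assert tiny_dataset.environments == [0, 1]
    sub = tiny_dataset.subset_rows(np.arange(10))
    assert sub.n == 10
    assert sub.xs(("a",)).shape == (10, 1)
    assert tiny_dataset.xs(()).shape == (tiny_dataset.n, 0)
    with pytest.raises(ConfigError):
        tiny_dataset.xs(("nope",))


def test_propensity_of_treat_binary_only(tiny_dataset):
    p1 = tiny_dataset.propensity_of_treat()
    np.testing.assert_allclose(p1, np.full(tiny_dataset.n, 0.5))
    multi = MultiEnvDataset(y=[0.0, 1.0, 2.0],
                            x=pd.DataFrame({"a": [0.0, 1.0, 2.0]}),
                            t=[0, 1, 2], env=[0, 0, 0], prop=[0.3, 0.3, 0.4])
    with pytest.raises(UnsupportedTreatmentError):
        multi.propensity_of_treat()


# ---------------------------------------------------------------------------
# Policies
# ---------------------------------------------------------------------------

def test_constant_policy_is_deterministic():
    pol = make_constant_policy(1, TreatmentSpace(k=3))
    probs = pol.prob_matrix(pd.DataFrame({"a": [0.0, 1.0]}))
    np.testing.assert_allclose(probs, [[0, 1, 0], [0, 1, 0]])


def test_bernoulli_policy_bounds():
    with pytest.raises(ConfigError):
        make_bernoulli_policy(0.0)
    pol = make_bernoulli_policy(0.25)
    np.testing.assert_allclose(pol.action_prob({"a": 1.0}), [0.75, 0.25])


def test_policy_sampling_matches_probs():
    pol = make_bernoulli_policy(0.3)
    rng = np.random.default_rng(0)
    x = pd.DataFrame({"a": np.zeros(20000)})
    actions, prop = pol.sample(x, rng)
    assert abs(actions.mean() - 0.3) < 0.02
    np.testing.assert_allclose(prop, np.where(actions == 1, 0.3, 0.7))


def test_policy_rejects_bad_output():
    bad = Policy(lambda x: np.full((len(x), 2), 0.7), k=2)
    with pytest.raises(ConfigError):
        bad.prob_matrix(pd.DataFrame({"a": [1.0]}))


# ---------------------------------------------------------------------------
# CATEFunction / SubsetTestResult
# ---------------------------------------------------------------------------

def test_cate_baseline_is_exact_zero():
    cate = CATEFunction(subset=("a",), fn=lambda xs, t: 1.0 + xs[:, 0])
    xs = np.array([[1.0], [2.0]])
    np.testing.assert_array_equal(cate(xs, 0), [0.0, 0.0])
    np.testing.assert_allclose(cate(xs, 1), [2.0, 3.0])


def test_subset_test_result_reject_consistency():
    res = SubsetTestResult(subset=("a",), method="wald", statistic=5.0,
                           df=2, p_value=0.01, alpha=0.05)
    assert res.reject
    assert not SubsetTestResult(subset=("a",), method="wald", statistic=1.0,
                                df=2, p_value=0.5, alpha=0.05).reject
    with pytest.raises(ConfigError):
        SubsetTestResult(subset=(), method="dr", statistic=0.0, df=1,
                         p_value=1.5, alpha=0.05)


# ---------------------------------------------------------------------------
# Pseudo-outcomes
# ---------------------------------------------------------------------------

def test_pseudo_outcome_scalar_formula():
    mu = lambda x, t: 2.0 if t == 1 else 1.0
    pi = lambda t, x: 0.25 if t == 1 else 0.75
    got = pseudo_outcome(y=3.0, x=[0.0], t=1, mu_bar=mu, pi_bar=pi, env=0)
    # (mu1 - mu0) + (y - mu1)/pi1 = 1 + 1/0.25
    assert got == pytest.approx(1.0 + 4.0)
    got0 = pseudo_outcome(y=3.0, x=[0.0], t=0, mu_bar=mu, pi_bar=pi, env=0)
    # (mu1 - mu0) - (y - mu0)/(1 - pi1) = 1 - 2/0.75
    assert got0 == pytest.approx(1.0 - 2.0 / 0.75)


def test_pseudo_outcome_rejects_multilevel():
    with pytest.raises(UnsupportedTreatmentError):
        pseudo_outcome(1.0, [0.0], 2, lambda x, t: 0.0,
                       lambda t, x: 0.5, env=0)


def test_pseudo_outcomes_conditional_mean_is_cate(tiny_dataset):
    # perfect mu models and known propensities: mean of o ~ mean CATE
    mu = {e: (lambda x_df, t:
              1.0 + np.asarray(x_df)[:, 0]
              + t * (0.5 + np.asarray(x_df)[:, 1]))
          for e in tiny_dataset.environments}
    o = pseudo_outcomes(tiny_dataset, mu, tiny_dataset.propensity_of_treat())
    truth = 0.5 + tiny_dataset.x["b"].to_numpy()
    assert abs(np.mean(o - truth)) < 0.4


def test_pseudo_outcomes_allows_degenerate_complement():
    # prop of the taken action is fine even when the other arm's
    # probability underflows to zero
    x = pd.DataFrame({"a": [0.0] * 4})
    data = MultiEnvDataset(y=[1.0, 2.0, 0.5, 1.5], x=x, t=[1, 1, 0, 0],
                           env=[0, 0, 0, 0], prop=[1.0, 1.0, 1.0, 1.0])
    mu = {0: lambda x_df, t: np.zeros(len(x_df))}
    o = pseudo_outcomes(data, mu, data.propensity_of_treat())
    assert np.all(np.isfinite(o))


# ---------------------------------------------------------------------------
# Splitting, pooled CATE, argmax probabilities
# ---------------------------------------------------------------------------

def test_stratified_split_partition(tiny_dataset):
    i1, i2 = stratified_split_indices(tiny_dataset, 0.5, seed=0)
    assert len(np.intersect1d(i1, i2)) == 0
    assert len(i1) + len(i2) == tiny_dataset.n
    j1, j2 = stratified_split_indices(tiny_dataset, 0.5, seed=0)
    np.testing.assert_array_equal(i1, j1)
    np.testing.assert_array_equal(i2, j2)
    # both halves contain every env x arm stratum
    for idx in (i1, i2):
        sub = tiny_dataset.subset_rows(idx)
        for e in (0, 1):
            for arm in (0, 1):
                assert np.any((sub.env == e) & (sub.t == arm))


def test_stratified_split_needs_two_per_stratum():
    x = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0]})
    data = MultiEnvDataset(y=[0.0] * 4, x=x, t=[0, 0, 0, 1],
                           env=[0, 0, 0, 0], prop=[0.5] * 4)
    with pytest.raises(ConfigError):
        stratified_split_indices(data, 0.5, seed=0)


def test_pooled_cate_recovers_linear_effect(tiny_dataset):
    cate = pooled_cate_fit(tiny_dataset, ("b",), seed=1)
    grid = np.array([[-1.0], [0.0], [1.0]])
    got = cate(grid, 1)
    want = 0.5 + grid[:, 0]
    assert np.max(np.abs(got - want)) < 0.4
    np.testing.assert_array_equal(cate(grid, 0), np.zeros(3))


def test_pooled_cate_empty_subset_is_constant(tiny_dataset):
    cate = pooled_cate_fit(tiny_dataset, (), seed=1)
    got = cate(np.empty((5, 0)), 1)
    assert np.all(got == got[0])


def test_argmax_policy_probs_ties_split_uniformly():
    probs = argmax_policy_probs(np.array([[0.0, 1.0, 1.0], [0.0, -1.0, -2.0]]))
    np.testing.assert_allclose(probs, [[0.0, 0.5, 0.5], [1.0, 0.0, 0.0]])
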