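"""Nonparametric DR-learner test for effect-invariance.

Pipeline: split the sample in half (stratified by environment and arm), fit
per-environment outcome regressions and a propensity model on the first half,
form doubly robust pseudo-outcomes on the second half, and test whether the
conditional mean of the pseudo-outcome given the subset covariates is the
same in every environment.  The final test is a multi-environment version of
the generalised covariance measure (GCM): residualize the pseudo-outcome and
reference-coded environment indicators on the subset covariates, and compare
the vector of normalized residual products against its estimated covariance
with a chi-squared reference distribution (``l - 1`` degrees of freedom).

Because the pseudo-outcome is doubly robust, the test keeps its level when
either the outcome models or the propensities are correct, and it places no
parametric restrictions on the CATE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .core import (ConfigError, MultiEnvDataset, SubsetTestResult,
                   fit_mu_models, pseudo_outcomes, stratified_split_indices)


def make_regressor(spec, seed: int = 0):
    """Resolve a regression spec: ``'forest'``, ``'poly'``, ``'linear'`` or an estimator."""
    if spec is None or spec == "forest":
        return RandomForestRegressor(n_estimators=50, min_samples_leaf=10,
                                     random_state=seed)
    if spec == "poly":
        return make_pipeline(PolynomialFeatures(3, include_bias=False),
                             Ridge(alpha=1e-3))
    if spec == "linear":
        return LinearRegression()
    return clone(spec)


@dataclass
class NuisanceModels:
    """Fitted nuisances: per-environment ``mu_e(x, t)`` and a propensity model."""

    mu_bar: dict
    known_propensities: bool
    fit_indices: np.ndarray
    _pi_model: object | None = None

    def pi_treat(self, data: MultiEnvDataset) -> np.ndarray:
        """Modelled ``pi(1 | x_i)`` per record of ``data``."""
        if self.known_propensities:
            return data.propensity_of_treat()
        proba = self._pi_model.predict_proba(data.x.to_numpy(float))[:, 1]
        return np.clip(proba, 1e-3, 1 - 1e-3)


def split_sample(data: MultiEnvDataset, fraction: float = 0.5,
                 seed: int = 0) -> tuple[MultiEnvDataset, MultiEnvDataset]:
    """Disjoint exhaustive split stratified by environment x treatment arm."""
    i1, i2 = stratified_split_indices(data, fraction, seed)
    return data.subset_rows(i1), data.subset_rows(i2)


def fit_nuisances(d1: MultiEnvDataset, learner_spec=None,
                  known_propensities: bool = True,
                  seed: int = 0) -> NuisanceModels:
    """Fit per-environment outcome regressions (and optionally a propensity model)."""
    mu = fit_mu_models(d1, make_regressor(learner_spec, seed))
    pi_model = None
    if not known_propensities:
        pi_model = LogisticRegression(max_iter=1000)
        pi_model.fit(d1.x.to_numpy(float), d1.t)
    return NuisanceModels(mu_bar=mu, known_propensities=known_propensities,
                          fit_indices=np.arange(d1.n), _pi_model=pi_model)


def _cross_fit_mean(x: np.ndarray, y: np.ndarray, spec, seed: int) -> np.ndarray:
    """Out-of-fold conditional-mean predictions of ``y`` given ``x`` (2 folds)."""
    n = len(y)
    if x.shape[1] == 0:
        # conditioning on the empty set: out-of-fold mean
        out = np.empty(n)
        for tr, te in KFold(2, shuffle=True, random_state=seed).split(x):
            out[te] = y[tr].mean()
        return out
    out = np.empty(n)
    for k, (tr, te) in enumerate(
            KFold(2, shuffle=True, random_state=seed).split(x)):
        m = make_regressor(spec, seed + 13 * k)
        m.fit(x[tr], y[tr])
        out[te] = m.predict(x[te])
    return out


def _cross_fit_proba(x: np.ndarray, ind: np.ndarray, seed: int) -> np.ndarray:
    """Out-of-fold ``P(ind = 1 | x)`` from a polynomial logistic classifier.

    Environment indicators are residualized with a classifier rather than a
    regressor so that the fitted conditional mean stays inside ``[0, 1]``:
    unbounded regressors extrapolate badly in the covariate tails, exactly
    where the doubly robust pseudo-outcome noise is heaviest, and the
    resulting residual products inflate the test level.
    """
    n = len(ind)
    if x.shape[1] == 0:
        out = np.empty(n)
        for tr, te in KFold(2, shuffle=True, random_state=seed).split(ind):
            out[te] = ind[tr].mean()
        return out
    out = np.empty(n)
    for tr, te in KFold(2, shuffle=True, random_state=seed).split(x):
        if len(np.unique(ind[tr])) < 2:
            out[te] = float(ind[tr].mean())
            continue
        m = make_pipeline(PolynomialFeatures(3, include_bias=False),
                          StandardScaler(),
                          LogisticRegression(max_iter=1000, C=10.0))
        m.fit(x[tr], ind[tr])
        out[te] = m.predict_proba(x[te])[:, 1]
    return out


def gcm_mean_equality_test(o: np.ndarray, xs: np.ndarray, env: np.ndarray,
                           regression_spec=None, weights: np.ndarray | None = None,
                           seed: int = 0) -> tuple[float, int, float]:
    """Multi-environment GCM: equality of ``E[o | x_S]`` across environments.

    Residualizes ``o`` on ``x_S`` with a pooled cross-fitted regression,
    residualizes each of the ``l - 1`` reference-coded environment indicators
    with a cross-fitted probability classifier (bounded in ``[0, 1]``), and
    aggregates the normalized residual-product sums into a chi-squared
    statistic with ``l - 1`` degrees of freedom.  Optional record weights
    multiply the residual products; a 1-D array applies the same weight to
    every environment contrast, an ``(n, l - 1)`` array weights each
    contrast separately.
    """
    o = np.asarray(o, dtype=float)
    xs = np.atleast_2d(np.asarray(xs, dtype=float))
    if xs.shape[0] != len(o):
        xs = xs.T
    env = np.asarray(env)
    envs = sorted(pd.unique(env).tolist())
    if len(envs) < 2:
        raise ConfigError("the environment column is constant; need l >= 2")
    n = len(o)
    r_o = o - _cross_fit_mean(xs, o, regression_spec, seed)
    prods = []
    for e in envs[1:]:
        ind = (env == e).astype(float)
        r_e = ind - _cross_fit_proba(xs, ind, seed)
        prods.append(r_o * r_e)
    p = _apply_weights(np.column_stack(prods), weights)
    mean_p = p.mean(axis=0)
    sigma = (p.T @ p) / n - np.outer(mean_p, mean_p)
    stat = float(n * mean_p @ np.linalg.pinv(sigma, hermitian=True) @ mean_p)
    df = len(envs) - 1
    return stat, df, float(chi2.sf(stat, df))


def _apply_weights(p: np.ndarray, weights) -> np.ndarray:
    if weights is None:
        return p
    w = np.asarray(weights, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    if w.shape[0] != p.shape[0] or w.shape[1] not in (1, p.shape[1]):
        raise ConfigError("weights shape does not match the residual products")
    return p * w


def direction_weights(o: np.ndarray, xs: np.ndarray, env: np.ndarray,
                      seed: int = 0) -> np.ndarray:
    """Cross-fitted sign weights aligning the residual products with the
    estimated between-environment gap.

    For each non-reference environment the gap ``E[o | x_S, e] - E[o | x_S,
    reference]`` is estimated on one fold and its out-of-fold sign is used as
    a weight function of ``x_S``.  Because the weight depends only on ``x_S``
    (and an independent fold), the weighted products keep a zero conditional
    mean under the null; under slope-type alternatives whose gap changes sign
    across the covariate range, the unweighted product mean integrates to
    zero while the sign-weighted mean does not.
    """
    envs = sorted(pd.unique(env).tolist())
    n = len(o)
    if xs.shape[1] == 0 or len(envs) < 2:
        return np.ones((n, len(envs) - 1 if len(envs) > 1 else 1))
    w = np.ones((n, len(envs) - 1))
    ref = envs[0]
    for j, e in enumerate(envs[1:]):
        for tr, te in KFold(2, shuffle=True,
                            random_state=seed + 17 * j).split(xs):
            tr_e = tr[env[tr] == e]
            tr_r = tr[env[tr] == ref]
            if len(tr_e) < 2 or len(tr_r) < 2:
                continue
            m_e = make_regressor("poly").fit(xs[tr_e], o[tr_e])
            m_r = make_regressor("poly").fit(xs[tr_r], o[tr_r])
            gap = m_e.predict(xs[te]) - m_r.predict(xs[te])
            sign = np.sign(gap)
            sign[sign == 0] = 1.0
            w[te, j] = sign
    return w


def _nuisance_direction_weights(nuis: NuisanceModels, d1: MultiEnvDataset,
                                d2: MultiEnvDataset,
                                subset: tuple[str, ...]) -> np.ndarray | None:
    """Direction weights learned entirely on the nuisance half.

    The per-environment outcome models fitted on ``d1`` imply an effect
    ``mu_e(x, 1) - mu_e(x, 0)``; its polynomial projection onto ``x_S`` is
    fitted on the ``d1`` covariates, and the sign of the between-environment
    projection gap is evaluated on ``d2``.  Everything defining the weight is
    a function of ``d1`` and of ``x_S`` only, so on the test half the
    weighted residual products keep a zero conditional mean under the null
    and the weight cannot align with the test-half estimation errors.
    """
    envs = d2.environments
    if len(subset) == 0 or len(envs) < 2:
        return None
    xs1 = d1.xs(subset)
    x1 = d1.x
    proj = {}
    for e in envs:
        eff = nuis.mu_bar[e](x1, 1) - nuis.mu_bar[e](x1, 0)
        proj[e] = make_regressor("poly").fit(xs1, eff)
    xs2 = d2.xs(subset)
    w = np.ones((d2.n, len(envs) - 1))
    ref_pred = proj[envs[0]].predict(xs2)
    for j, e in enumerate(envs[1:]):
        sign = np.sign(proj[e].predict(xs2) - ref_pred)
        sign[sign == 0] = 1.0
        w[:, j] = sign
    return w


@dataclass
class DRTestConfig:
    """Configuration of the DR-learner e-invariance test."""

    fraction: float = 0.5
    seed: int = 0
    mu_learner: object = "forest"
    regression_spec: object = "poly"
    known_propensities: bool = True
    per_env_residualization: bool = False
    direction_weight: bool = True
    weights_fn: Callable | None = None


def dr_einv_test(data: MultiEnvDataset, subset: Sequence[str],
                 alpha: float = 0.05,
                 config: DRTestConfig | None = None) -> SubsetTestResult:
    """DR-learner e-invariance test for one covariate subset."""
    cfg = config or DRTestConfig()
    subset = tuple(subset)
    d1, d2 = split_sample(data, cfg.fraction, cfg.seed)
    nuis = fit_nuisances(d1, cfg.mu_learner, cfg.known_propensities, cfg.seed)
    o = pseudo_outcomes(d2, nuis.mu_bar, nuis.pi_treat(d2))
    xs = d2.xs(subset)
    if cfg.weights_fn is not None:
        weights = cfg.weights_fn(d2)
    elif cfg.direction_weight:
        weights = _nuisance_direction_weights(nuis, d1, d2, subset)
    else:
        weights = None
    if cfg.per_env_residualization:
        # residualize o within each environment instead of pooled
        r_o = np.empty(d2.n)
        for e in d2.environments:
            m = d2.env == e
            r_o[m] = o[m] - _cross_fit_mean(xs[m], o[m], cfg.regression_spec,
                                            cfg.seed)
        stat, df, p_value = _gcm_from_residuals(r_o, xs, d2.env,
                                                cfg.regression_spec, weights,
                                                cfg.seed)
    else:
        stat, df, p_value = gcm_mean_equality_test(
            o, xs, d2.env, cfg.regression_spec, weights, cfg.seed)
    return SubsetTestResult(subset=subset, method="dr", statistic=stat,
                            df=df, p_value=p_value, alpha=alpha)


def _gcm_from_residuals(r_o: np.ndarray, xs: np.ndarray, env: np.ndarray,
                        regression_spec, weights, seed: int):
    envs = sorted(pd.unique(env).tolist())
    n = len(r_o)
    prods = []
    for e in envs[1:]:
        ind = (env == e).astype(float)
        r_e = ind - _cross_fit_proba(xs, ind, seed)
        prods.append(r_o * r_e)
    p = _apply_weights(np.column_stack(prods), weights)
    mean_p = p.mean(axis=0)
    sigma = (p.T @ p) / n - np.outer(mean_p, mean_p)
    stat = float(n * mean_p @ np.linalg.pinv(sigma, hermitian=True) @ mean_p)
    df = len(envs) - 1
    return stat, df, float(chi2.sf(stat, df))
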