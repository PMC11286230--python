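"""Zero-shot policy learning through effect-invariant covariate subsets.

Given multi-environment training data and covariate-only observations from an
unseen test environment, the learner (i) screens covariates, (ii) tests every
subset of the screened pool for effect-invariance, (iii) fits a pooled CATE
per accepted subset and converts it to an argmax policy, and (iv) picks the
accepted subset whose policy promises the largest average effect on the test
covariates.  Under invariance-transfer assumptions the resulting policy is
guaranteed to beat every constant (covariate-free) policy in any test
environment, and is worst-case optimal when some environment in the test
equivalence class gains nothing from non-invariant covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.preprocessing import StandardScaler

from .core import (CATEFunction, ConfigError, MultiEnvDataset, Policy,
                   SubsetTestResult, TreatmentSpace, argmax_policy_probs,
                   fit_mu_models, make_constant_policy, pooled_cate_fit,
                   pseudo_outcomes, stratified_split_indices)
from .dr_test import DRTestConfig, dr_einv_test
from .wald_test import wald_einv_test


@dataclass
class EInvSetCollection:
    """All tested subsets with their e-invariance test results."""

    accepted: list[SubsetTestResult]
    all_results: list[SubsetTestResult]
    alpha: float
    method: str
    screened_pool: tuple[str, ...]

    @property
    def accepted_subsets(self) -> list[tuple[str, ...]]:
        return [r.subset for r in self.accepted]


@dataclass
class ZeroShotResult:
    """Outcome of zero-shot policy learning."""

    s_star: tuple[str, ...] | None
    policy: Policy
    criterion: dict
    fallback_used: bool
    collection: EInvSetCollection | None
    cates: dict = field(default_factory=dict)


@dataclass
class ZeroShotConfig:
    """Configuration of :func:`learn_einv_policy`."""

    method: str = "wald"
    seed: int = 0
    max_pool: int = 10
    screen: bool = True
    candidate_pool: tuple[str, ...] | None = None
    dr_config: DRTestConfig | None = None
    cate_learner: object = None


def screen_variables(data: MultiEnvDataset, max_pool: int = 10,
                     seed: int = 0) -> list[str]:
    """L1-screen covariates by their relevance to the pooled CATE.

    Regresses DR pseudo-outcomes (nuisances on a held-out half) on the
    standardized covariates with a cross-validated Lasso and keeps covariates
    with nonzero coefficients, ordered by coefficient magnitude and capped at
    ``max_pool``.  The empty subset always remains testable downstream.
    """
    if data.x.shape[1] < 1:
        raise ConfigError("screening requires at least one covariate")
    i1, i2 = stratified_split_indices(data, 0.5, seed)
    d1, d2 = data.subset_rows(i1), data.subset_rows(i2)
    mu = fit_mu_models(d1)
    o = pseudo_outcomes(d2, mu, d2.propensity_of_treat())
    xz = StandardScaler().fit_transform(d2.x.to_numpy(float))
    lasso = LassoCV(cv=5, random_state=seed).fit(xz, o)
    coef = np.abs(lasso.coef_)
    order = np.argsort(-coef)
    names = [data.covariate_names[j] for j in order if coef[j] > 0]
    return names[:max_pool]


def _holm_combine(p_values: list[float]) -> float:
    """Overall p-value of the per-level tests under Holm's step-down rule.

    The subset is rejected when any level rejects after Holm correction,
    which happens exactly when ``m * min(p) < alpha``; the corresponding
    overall p-value is ``min(1, m * min(p))``.
    """
    if not p_values:
        return 1.0
    return min(1.0, len(p_values) * min(p_values))


def _test_subset(data: MultiEnvDataset, subset: tuple[str, ...], alpha: float,
                 method: str, cfg: ZeroShotConfig) -> SubsetTestResult:
    k = data.n_treatments
    if k <= 2:
        return _binary_test(data, subset, alpha, method, cfg)
    # multi-level treatment: per-level reduction against baseline 0 + Holm
    results = []
    for level in range(1, k):
        keep = np.isin(data.t, [0, level])
        sub = data.subset_rows(np.flatnonzero(keep))
        sub = MultiEnvDataset(y=sub.y, x=sub.x, t=(sub.t == level).astype(int),
                              env=sub.env, prop=sub.prop)
        results.append(_binary_test(sub, subset, alpha, method, cfg))
    p_adj = _holm_combine([r.p_value for r in results])
    worst = min(results, key=lambda r: r.p_value)
    return SubsetTestResult(subset=subset, method=worst.method,
                            statistic=worst.statistic, df=worst.df,
                            p_value=p_adj, alpha=alpha)


def _binary_test(data: MultiEnvDataset, subset: tuple[str, ...], alpha: float,
                 method: str, cfg: ZeroShotConfig) -> SubsetTestResult:
    if method == "wald":
        return wald_einv_test(data, subset, alpha=alpha)
    if method == "dr":
        return dr_einv_test(data, subset, alpha=alpha,
                            config=cfg.dr_config or DRTestConfig(seed=cfg.seed))
    raise ConfigError(f"unknown test method {method!r}")


def enumerate_and_test(data: MultiEnvDataset, alpha: float, method: str,
                       pool: Sequence[str],
                       cfg: ZeroShotConfig | None = None) -> EInvSetCollection:
    """Test every subset of ``pool`` (including the empty set) at level ``alpha``.

    Subsets are visited in size-then-lexicographic order.  Each subset is its
    own null hypothesis, so no multiple-testing correction is applied across
    subsets; all non-rejected subsets are returned as accepted.
    """
    cfg = cfg or ZeroShotConfig(method=method)
    pool = tuple(sorted(pool))
    all_results: list[SubsetTestResult] = []
    accepted: list[SubsetTestResult] = []
    for size in range(len(pool) + 1):
        for subset in combinations(pool, size):
            res = _test_subset(data, subset, alpha, method, cfg)
            all_results.append(res)
            if not res.reject:
                accepted.append(res)
    return EInvSetCollection(accepted=accepted, all_results=all_results,
                             alpha=alpha, method=method, screened_pool=pool)


def policy_from_cate(cate: CATEFunction) -> Policy:
    """Argmax policy: mass spread uniformly over effect-maximizing arms.

    The baseline arm competes with effect exactly zero, so covariate regions
    with a negative estimated effect receive the baseline treatment.
    """
    space = cate.space

    def fn(x_df: pd.DataFrame) -> np.ndarray:
        effects = np.zeros((len(x_df), space.k))
        for t in range(space.k):
            if t != space.t0:
                effects[:, t] = cate(x_df, t)
        return argmax_policy_probs(effects)

    return Policy(fn, k=space.k, support_subset=cate.subset,
                  name=f"argmax[{','.join(cate.subset) or 'const'}]")


def subset_selection_criterion(cate: CATEFunction, policy: Policy,
                               x_test: pd.DataFrame) -> float:
    """Average promised effect ``(1/m) sum_i sum_t tau(x_i, t) pi(t | x_i)``."""
    if policy.support_subset != cate.subset:
        raise ConfigError("policy support subset must match the CATE subset")
    x_test = pd.DataFrame(x_test)
    if len(x_test) == 0:
        raise ConfigError("x_test must contain at least one row")
    probs = policy.prob_matrix(x_test)
    total = np.zeros(len(x_test))
    for t in range(cate.space.k):
        total += cate(x_test, t) * probs[:, t]
    return float(total.mean())


def _fallback_constant_policy(train: MultiEnvDataset,
                              seed: int) -> tuple[Policy, float]:
    """Constant policy maximizing the pooled DR estimate of the ATE."""
    i1, i2 = stratified_split_indices(train, 0.5, seed)
    d1, d2 = train.subset_rows(i1), train.subset_rows(i2)
    mu = fit_mu_models(d1)
    ate = float(np.mean(pseudo_outcomes(d2, mu, d2.propensity_of_treat())))
    best_t = 1 if ate > 0 else 0
    return make_constant_policy(best_t, TreatmentSpace()), ate


def learn_einv_policy(train: MultiEnvDataset, x_test: pd.DataFrame,
                      alpha: float = 0.05,
                      config: ZeroShotConfig | None = None) -> ZeroShotResult:
    """Learn a policy for a covariate-only test environment.

    Screens covariates, tests all subsets of the pool for effect-invariance,
    fits a pooled CATE and an argmax policy per accepted subset, scores each
    on the test covariates and returns the policy of the best-scoring subset
    (ties broken by a seeded uniform draw).  If no subset is accepted, the
    constant policy maximizing the pooled average treatment effect is
    returned with ``fallback_used=True``.
    """
    cfg = config or ZeroShotConfig()
    x_test = pd.DataFrame(x_test)
    missing = [c for c in x_test.columns if c not in train.covariate_names]
    if missing:
        raise ConfigError(f"test covariates {missing} not present in training data")
    if cfg.candidate_pool is not None:
        pool: Sequence[str] = cfg.candidate_pool
    elif cfg.screen:
        pool = screen_variables(train, cfg.max_pool, cfg.seed)
    else:
        pool = train.covariate_names[:cfg.max_pool]
    coll = enumerate_and_test(train, alpha, cfg.method, pool, cfg)
    if not coll.accepted:
        policy, _ = _fallback_constant_policy(train, cfg.seed)
        return ZeroShotResult(s_star=None, policy=policy, criterion={},
                              fallback_used=True, collection=coll)
    criterion: dict = {}
    policies: dict = {}
    cates: dict = {}
    for res in coll.accepted:
        cate = pooled_cate_fit(train, res.subset, learner=cfg.cate_learner,
                               seed=cfg.seed)
        pol = policy_from_cate(cate)
        criterion[res.subset] = subset_selection_criterion(cate, pol, x_test)
        policies[res.subset] = pol
        cates[res.subset] = cate
    values = np.array([criterion[s] for s in criterion])
    best = values.max()
    tied = [s for s, v in criterion.items() if best - v <= 1e-12]
    rng = np.random.default_rng(cfg.seed)
    s_star = tied[rng.integers(len(tied))] if len(tied) > 1 else tied[0]
    return ZeroShotResult(s_star=s_star, policy=policies[s_star],
                          criterion=criterion, fallback_used=False,
                          collection=coll, cates=cates)
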