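"""Few-shot CATE estimation constrained by a training-environment invariance.

With a small outcome-labelled sample from the test environment and an
effect-invariant subset ``S`` learned on the training environments, the test
CATE is estimated under the separability assumption

    tau_test(x, t) = f(x_S, t) + g(x_N, t),      N = complement of S,

whose invariance constraint ``E[tau_test(X, t) | X_S] = tau_tr(x_S, t)``
pins down ``f`` in terms of ``g``:

    tau_test(x, t) = tau_tr(x_S, t) - E[g(X_N, t) | X_S = x_S] + g(x_N, t).

With a linear class for ``g`` (per treatment contrast, no intercept -- the
level is carried by ``tau_tr``) and a linear projector ``q(x_S) = E[x_N | x_S]``
refit on the test sample, the squared-error fit against DR pseudo-outcomes
reduces to ordinary least squares on the centered regressors
``x_N - q(x_S)``, so only ``|N|`` free parameters are estimated from the
small test sample instead of a full CATE surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from .core import (CATEFunction, ConfigError, DegenerateDesignError,
                   MultiEnvDataset, Policy, fit_mu_models, pseudo_outcomes,
                   stratified_split_indices)
from .zero_shot import policy_from_cate


@dataclass
class SeparableCATEModel:
    """Separable test-environment CATE built around an invariant component.

    The implied effect is ``tau(x, 1) = tau_tr(x_S, 1) - g_coef' q(x_S)
    + g_coef' x_N``; the baseline arm is identically zero.
    """

    subset_S: tuple[str, ...]
    subset_N: tuple[str, ...]
    g_coef: np.ndarray
    projector: Callable[[np.ndarray], np.ndarray]
    tau_tr: CATEFunction

    @property
    def implied_tau(self) -> CATEFunction:
        return tau_from_g(self.g_coef, self.tau_tr, self.projector,
                          self.subset_N)


def _linear_projector(xs: np.ndarray, xn: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Fit ``q(x_S) = E[x_N | x_S]`` by per-coordinate linear regression."""
    if xn.shape[1] == 0:
        def proj_empty(xs_new: np.ndarray) -> np.ndarray:
            return np.empty((len(np.atleast_2d(xs_new)), 0))

        return proj_empty
    if xs.shape[1] == 0:
        means = xn.mean(axis=0)

        def proj(xs_new: np.ndarray, _m=means) -> np.ndarray:
            return np.tile(_m, (len(np.atleast_2d(xs_new)), 1))

        return proj
    model = LinearRegression().fit(xs, xn)

    def proj(xs_new: np.ndarray, _m=model) -> np.ndarray:
        out = _m.predict(np.atleast_2d(np.asarray(xs_new, dtype=float)))
        return np.atleast_2d(out)

    return proj


def tau_from_g(g_coef: np.ndarray, tau_tr: CATEFunction,
               projector: Callable[[np.ndarray], np.ndarray],
               subset_N: Sequence[str]) -> CATEFunction:
    """Implied test-environment CATE ``tau_tr(x_S) - g'q(x_S) + g'x_N``."""
    g_coef = np.asarray(g_coef, dtype=float)
    subset_N = tuple(subset_N)
    if len(g_coef) != len(subset_N):
        raise ConfigError("g_coef length must match the complement subset")
    full_subset = tuple(tau_tr.subset) + subset_N
    n_s = len(tau_tr.subset)

    def fn(x_arr: np.ndarray, t: int) -> np.ndarray:
        x_arr = np.atleast_2d(np.asarray(x_arr, dtype=float))
        xs, xn = x_arr[:, :n_s], x_arr[:, n_s:]
        base = tau_tr(xs, t)
        if len(g_coef) == 0:
            return base
        return base - projector(xs) @ g_coef + xn @ g_coef

    return CATEFunction(subset=full_subset, fn=fn, space=tau_tr.space)


def few_shot_fit(test_data: MultiEnvDataset, tau_tr: CATEFunction,
                 g_class: str = "linear", seed: int = 0,
                 nuisance_learner=None) -> SeparableCATEModel:
    """Fit the separable model on a small single-environment test sample.

    Builds DR pseudo-outcomes on the test sample (nuisances on a seeded
    half-split, propensities from the recorded ``prop``), refits the linear
    projector ``q`` on the test covariates and solves the closed-form least
    squares in the centered complement covariates.
    """
    if g_class != "linear":
        raise ConfigError("only the linear g-class is implemented as default")
    if len(test_data.environments) != 1:
        raise ConfigError("few-shot fitting expects a single test environment")
    subset_S = tuple(tau_tr.subset)
    subset_N = tuple(c for c in test_data.covariate_names if c not in subset_S)
    if test_data.n < len(subset_N) + 1:
        raise ConfigError(
            f"need at least {len(subset_N) + 1} test records for the linear class")
    i1, i2 = stratified_split_indices(test_data, 0.5, seed)
    d1, d2 = test_data.subset_rows(i1), test_data.subset_rows(i2)
    mu = fit_mu_models(d1, nuisance_learner)
    o = pseudo_outcomes(d2, mu, d2.propensity_of_treat())
    xs = d2.xs(subset_S)
    xn = d2.xs(subset_N)
    projector = _linear_projector(test_data.xs(subset_S),
                                  test_data.xs(subset_N))
    if not subset_N:
        return SeparableCATEModel(subset_S=subset_S, subset_N=(),
                                  g_coef=np.empty(0), projector=projector,
                                  tau_tr=tau_tr)
    centered = xn - projector(xs)
    target = o - tau_tr(xs, 1)
    rank = np.linalg.matrix_rank(centered)
    if rank < centered.shape[1]:
        raise DegenerateDesignError(
            "centered complement design is rank deficient")
    g_coef, *_ = np.linalg.lstsq(centered, target, rcond=None)
    return SeparableCATEModel(subset_S=subset_S, subset_N=subset_N,
                              g_coef=g_coef, projector=projector,
                              tau_tr=tau_tr)


def few_shot_policy(model: SeparableCATEModel) -> Policy:
    """Argmax policy over the implied test-environment CATE (uniform ties)."""
    return policy_from_cate(model.implied_tau)


def unconstrained_dr_fit(test_data: MultiEnvDataset, seed: int = 0,
                         nuisance_learner=None) -> CATEFunction:
    """Plain DR-learner CATE on the test sample alone (comparison baseline)."""
    subset = tuple(test_data.covariate_names)
    i1, i2 = stratified_split_indices(test_data, 0.5, seed)
    d1, d2 = test_data.subset_rows(i1), test_data.subset_rows(i2)
    mu = fit_mu_models(d1, nuisance_learner)
    o = pseudo_outcomes(d2, mu, d2.propensity_of_treat())
    model = LinearRegression().fit(d2.xs(subset), o)

    def fn(x_arr: np.ndarray, t: int, _m=model) -> np.ndarray:
        return _m.predict(np.atleast_2d(np.asarray(x_arr, dtype=float)))

    return CATEFunction(subset=subset, fn=fn)
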