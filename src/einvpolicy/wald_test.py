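"""Wald test for effect-invariance under linear CATEs.

The test works with a (potentially misspecified) response model

    alpha' X~  +  u_e A X~   (main effect)
    + c * beta' X~S  +  c * u_e B X~S   (treatment and environment x treatment effect)

where ``X~ = (1, x)``, ``X~S = (1, x_S)``, ``u_e`` one-hot encodes the
environment and ``c = 1{t=1} - pi~(1|x_S)`` is the treatment indicator
centered by a fixed policy ``pi~`` that depends only on ``x_S``.  Estimation
is by weighted least squares with weights ``W_i = pi~(t_i|x_S_i) / prop_i``;
the combination of centering and weighting yields a Neyman-orthogonal score,
so the treatment-effect estimates stay consistent even when the main effect
is misspecified.  The environment-by-treatment interaction ``B`` vanishes
exactly when the subset is effect-invariant, so the test rejects when the
Wald quadratic form in ``vec(B_hat)`` with a sandwich covariance exceeds a
chi-squared quantile.

A naive parameterization with a full one-hot ``A, B`` next to global
``alpha, beta`` is rank deficient; this module uses reference coding (the
first environment's main effect absorbed into ``alpha`` and its interaction
into ``beta``), giving ``(l-1)(1+|S|)`` degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.stats import chi2

from .core import (ConfigError, DegenerateDesignError, MultiEnvDataset,
                   Policy, PositivityError, SubsetTestResult,
                   UnsupportedTreatmentError, make_bernoulli_policy)

#: Relative threshold below which singular values of the design count as zero.
RANK_RTOL = 1e-10


@dataclass
class WaldModelFit:
    """Weighted least-squares fit of the environment-interacted response model.

    ``V_hat`` estimates the covariance of ``sqrt(n) * (vec(B_hat) - vec(B))``
    (the lower ``q x q`` sandwich block), with ``q = (l-1)(1+|S|)``.
    """

    subset: tuple[str, ...]
    environments: list
    alpha_hat: np.ndarray
    A_hat: np.ndarray
    beta_hat: np.ndarray
    B_hat: np.ndarray
    V_hat: np.ndarray
    n: int
    s_dim: int
    q_dim: int
    column_names: list[str]


def _check_pi_tilde(pi_tilde: Policy, subset: tuple[str, ...]) -> None:
    if pi_tilde.support_subset is None:
        raise ConfigError(
            "the centering policy must declare its support_subset so that "
            "membership in Pi_S can be verified")
    extra = set(pi_tilde.support_subset) - set(subset)
    if extra:
        raise ConfigError(
            f"centering policy depends on non-subset covariates {sorted(extra)}")


def center_treatment(t: int, xS, pi_tilde: Policy) -> float:
    """Centered treatment indicator ``1{t=1} - pi~(1 | x_S)`` for one record."""
    p = pi_tilde.action_prob(xS)
    return float((t == 1) - p[1])


def _pi_tilde_probs(pi_tilde: Policy, data: MultiEnvDataset) -> np.ndarray:
    """``pi~(1 | x_S_i)`` per record."""
    return pi_tilde.prob_matrix(data.x)[:, 1]


def compute_weights(data: MultiEnvDataset, subset: Sequence[str],
                    pi_tilde: Policy) -> np.ndarray:
    """Policy-ratio weights ``W_i = pi~(t_i | x_S_i) / prop_i``."""
    subset = tuple(subset)
    _check_pi_tilde(pi_tilde, subset)
    if np.any(data.prop <= 0):
        raise PositivityError("recorded action probabilities must be positive")
    p1 = _pi_tilde_probs(pi_tilde, data)
    num = np.where(data.t == 1, p1, 1.0 - p1)
    return num / data.prop


def _build_design(data: MultiEnvDataset, subset: tuple[str, ...],
                  centered: np.ndarray) -> tuple[np.ndarray, list[str], list]:
    envs = data.environments
    if len(envs) < 2:
        raise ConfigError("need at least 2 environments for an invariance test")
    x_full = np.column_stack([np.ones(data.n), data.x.to_numpy(float)])
    xs = np.column_stack([np.ones(data.n), data.xs(subset)])
    full_names = ["1"] + data.covariate_names
    s_names = ["1"] + list(subset)
    cols = [x_full]
    names = [f"alpha:{c}" for c in full_names]
    for e in envs[1:]:
        ind = (data.env == e).astype(float)[:, None]
        cols.append(ind * x_full)
        names += [f"A[{e}]:{c}" for c in full_names]
    cols.append(centered[:, None] * xs)
    names += [f"beta:{c}" for c in s_names]
    for e in envs[1:]:
        ind = (data.env == e).astype(float)[:, None]
        cols.append(centered[:, None] * ind * xs)
        names += [f"B[{e}]:{c}" for c in s_names]
    return np.column_stack(cols), names, envs


def fit_gmm(data: MultiEnvDataset, subset: Sequence[str],
            pi_tilde: Policy | None = None,
            leverage_correction: bool = True) -> WaldModelFit:
    """Solve the centered/weighted estimating equations and the sandwich covariance.

    With the response model linear in its parameters the estimating equations
    reduce to weighted least squares; the covariance of the estimates is the
    method-of-moments sandwich ``J^-1 mean(G G') J^-T`` whose lower
    ``q x q`` block covers ``vec(B_hat)``.
    """
    subset = tuple(subset)
    if data.n == 0:
        raise DegenerateDesignError("empty dataset")
    if data.t.max() > 1:
        raise UnsupportedTreatmentError(
            "the Wald test fits a binary treatment; reduce multi-level "
            "treatments per level against the baseline")
    if pi_tilde is None:
        pi_tilde = make_bernoulli_policy(0.5)
    _check_pi_tilde(pi_tilde, subset)
    w = compute_weights(data, subset, pi_tilde)
    centered = data.t - _pi_tilde_probs(pi_tilde, data)
    z, names, envs = _build_design(data, subset, centered)
    n, p = z.shape
    sw = np.sqrt(w)
    zw = z * sw[:, None]
    yw = data.y * sw

    # rank check with column pivoting so rank deficiency names its columns
    _, r, piv = linalg.qr(zw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > RANK_RTOL * diag.max())) if diag.size else 0
    if rank < p:
        bad = [names[j] for j in piv[rank:]]
        raise DegenerateDesignError(
            f"design is rank deficient; offending column(s): {bad}")

    theta, *_ = np.linalg.lstsq(zw, yw, rcond=None)
    resid = data.y - z @ theta

    j_bar = -(zw.T @ zw) / n              # mean Jacobian of G_i
    j_inv = np.linalg.inv(j_bar)
    scale = np.ones(n)
    if leverage_correction:
        # HC3-style leverage rescaling of the moment contributions; guards the
        # finite-sample level when the policy-ratio weights are heavy tailed
        h = np.einsum("ij,jk,ik->i", zw, -j_inv, zw) / n
        scale = 1.0 / np.clip(1.0 - h, 0.05, None)
    g = (w * resid * scale)[:, None] * z  # moment contributions G_i
    omega = (g.T @ g) / n
    v_full = j_inv @ omega @ j_inv.T

    d = data.x.shape[1]
    n_env = len(envs)
    p_full, p_s = 1 + d, 1 + len(subset)
    s_dim = p_full * n_env + p_s
    q_dim = (n_env - 1) * p_s
    alpha_hat = theta[:p_full]
    a_hat = theta[p_full:p_full * n_env].reshape(n_env - 1, p_full)
    beta_hat = theta[p_full * n_env:p_full * n_env + p_s]
    b_hat = theta[s_dim:].reshape(n_env - 1, p_s)
    v_hat = v_full[s_dim:, s_dim:]
    return WaldModelFit(subset=subset, environments=envs, alpha_hat=alpha_hat,
                        A_hat=a_hat, beta_hat=beta_hat, B_hat=b_hat,
                        V_hat=v_hat, n=n, s_dim=s_dim, q_dim=q_dim,
                        column_names=names)


def wald_einv_test(data: MultiEnvDataset, subset: Sequence[str],
                   alpha: float = 0.05, pi_tilde: Policy | None = None,
                   propensities_estimated: bool = False,
                   leverage_correction: bool = True) -> SubsetTestResult:
    """Wald e-invariance test: ``T_n = n vec(B)' V^+ vec(B)`` against chi-squared.

    Rejects the hypothesis that the CATE given the subset is the same function
    in every training environment.  ``(l-1)(1+|S|)`` degrees of freedom under
    reference coding.  The covariance formula assumes the logging propensities
    in ``prop`` are known; set ``propensities_estimated=True`` to acknowledge
    estimated propensities (the test still runs, with a warning that the level
    guarantee then requires a covariance adjustment not implemented here).
    """
    if propensities_estimated:
        warnings.warn(
            "logging propensities flagged as estimated: the sandwich "
            "covariance ignores their estimation error, so the stated level "
            "is not guaranteed", UserWarning, stacklevel=2)
    fit = fit_gmm(data, subset, pi_tilde, leverage_correction=leverage_correction)
    b = fit.B_hat.ravel()
    v_inv = np.linalg.pinv(fit.V_hat, hermitian=True)
    stat = float(fit.n * b @ v_inv @ b)
    df = fit.q_dim
    p_value = float(chi2.sf(stat, df))
    return SubsetTestResult(subset=fit.subset, method="wald", statistic=stat,
                            df=df, p_value=p_value, alpha=alpha)
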