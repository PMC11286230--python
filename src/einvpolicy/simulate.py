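"""Seeded structural-causal-model simulators with ground-truth CATE oracles.

Three data-generating processes are provided:

* :func:`simulate_intro` -- a one-covariate SCM with an unobserved confounder
  ``U`` whose treatment effect ``1 + x`` is identical in every environment
  while the outcome level shifts with the environment.
* :func:`simulate_example1` -- a three-covariate SCM with two latent variables
  where only the subset ``{x2}`` carries an environment-invariant treatment
  effect; linear and nonlinear variants of the outcome equation are available.
* :func:`simulate_mrt_fixture` -- a micro-randomized-trial-like fixture with
  users as environments and per-user linear outcome models, emulating the
  structure of mobile-health suggestion trials.

Every generator returns a :class:`SimOutput` carrying the logged data, the
latent draws and an oracle for the invariant treatment-effect function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import (CATEFunction, ConfigError, MultiEnvDataset, Policy,
                   TreatmentSpace)

EXAMPLE1_VARIANTS = ("linear", "nonlinear_main", "nonlinear_cate")


@dataclass
class SimOutput:
    """Simulated data plus latent draws and the ground-truth CATE oracle.

    ``truth`` is the invariant CATE on ``truth_subset``; for generators whose
    effect varies by environment (the MRT fixture), ``truth_per_env`` maps
    each environment label to its own oracle.
    """

    data: MultiEnvDataset
    latent: pd.DataFrame
    truth: CATEFunction
    truth_subset: tuple[str, ...]
    truth_per_env: dict | None = None


def _sample_actions(policy: Policy, x: pd.DataFrame,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    return policy.sample(x, rng)


# ---------------------------------------------------------------------------
# Introductory one-covariate SCM
# ---------------------------------------------------------------------------

def simulate_intro(environments: Sequence[float], n_per_env: int,
                   policy: Policy | None = None, seed: int = 0,
                   treatment_mechanism: str = "linear_index") -> SimOutput:
    """Simulate ``U = eps_U; X = e*U + eps_X; Y = T(1+X) + X + 2e + U + eps_Y``.

    When ``policy`` is None the SCM's own mechanism assigns
    ``T = 1{1 + X + eps_T > 0}`` (``treatment_mechanism='linear_index'``) or
    ``T = 1{1/(1+X) + eps_T > 0}`` (``'reciprocal'``); the realized action
    probability is stored in ``prop`` either way.  The CATE given ``x`` equals
    ``1 + x`` in every environment.
    """
    if n_per_env < 0:
        raise ConfigError("n_per_env must be nonnegative")
    if treatment_mechanism not in ("linear_index", "reciprocal"):
        raise ConfigError(f"unknown treatment mechanism {treatment_mechanism!r}")
    rng = np.random.default_rng(seed)
    rows = []
    lat = []
    for e in environments:
        u = rng.standard_normal(n_per_env)
        x = e * u + rng.standard_normal(n_per_env)
        x_df = pd.DataFrame({"x": x})
        if policy is None:
            index = 1.0 + x if treatment_mechanism == "linear_index" \
                else 1.0 / (1.0 + x)
            t = (index + rng.standard_normal(n_per_env) > 0).astype(int)
            p_treat = norm.cdf(index)
            prop = np.where(t == 1, p_treat, 1.0 - p_treat)
        else:
            t, prop = _sample_actions(policy, x_df, rng)
        y = t * (1.0 + x) + x + 2.0 * e + u + rng.standard_normal(n_per_env)
        rows.append(pd.DataFrame({"y": y, "t": t, "env": e, "prop": prop,
                                  "x": x}))
        lat.append(pd.DataFrame({"u": u}))
    frame = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["y", "t", "env", "prop", "x"])
    truth = CATEFunction(subset=("x",),
                         fn=lambda xs, t: 1.0 + xs[:, 0])
    return SimOutput(data=MultiEnvDataset.from_frame(frame),
                     latent=pd.concat(lat, ignore_index=True) if lat
                     else pd.DataFrame(columns=["u"]),
                     truth=truth, truth_subset=("x",))


# ---------------------------------------------------------------------------
# Three-covariate SCM with two latent variables
# ---------------------------------------------------------------------------

def default_training_policy(x) -> np.ndarray:
    """Logistic logging policy ``P(T=1|x) = 1/(1 + exp(-0.5 + x1 - 0.5 x2 + 0.3 x3))``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    z = -0.5 + x[:, 0] - 0.5 * x[:, 1] + 0.3 * x[:, 2]
    return 1.0 / (1.0 + np.exp(z))


def make_default_training_policy() -> Policy:
    """The logistic logging policy of :func:`default_training_policy` as a Policy."""

    def fn(x_df: pd.DataFrame) -> np.ndarray:
        p = default_training_policy(x_df[["x1", "x2", "x3"]].to_numpy(float))
        return np.column_stack([1.0 - p, p])

    return Policy(fn, k=2, support_subset=("x1", "x2", "x3"),
                  name="logistic-logging")


def _as_param_tuple(p) -> tuple[float, float, float, float]:
    if isinstance(p, Mapping):
        return (float(p["gamma1"]), float(p["gamma2"]), float(p["gamma3"]),
                float(p["mu"]))
    p = tuple(float(v) for v in p)
    if len(p) != 4:
        raise ConfigError("env_params entries must be (gamma1, gamma2, gamma3, mu)")
    return p


def draw_env_params(n_env: int, seed: int, low: float = -3.0,
                    high: float = 3.0) -> list[tuple[float, float, float, float]]:
    """Independent Uniform[low, high] draws of (gamma1, gamma2, gamma3, mu) per environment."""
    rng = np.random.default_rng(seed)
    return [tuple(rng.uniform(low, high, size=4)) for _ in range(n_env)]


def example1_truth(variant: str) -> CATEFunction:
    """Ground-truth invariant CATE on ``{x2}`` for each outcome variant."""
    if variant in ("linear", "nonlinear_main"):
        fn = lambda xs, t: 1.0 + 0.5 * xs[:, 0]
    elif variant == "nonlinear_cate":
        fn = lambda xs, t: 1.0 + 0.5 * xs[:, 0] ** 2 + 0.5 * xs[:, 0] ** 3
    else:
        raise ConfigError(f"unknown variant {variant!r}; choose from {EXAMPLE1_VARIANTS}")
    return CATEFunction(subset=("x2",), fn=fn)


def simulate_example1(env_params: Sequence, n_per_env: int,
                      policy: Policy | None = None, variant: str = "linear",
                      seed: int = 0) -> SimOutput:
    """Simulate the three-covariate SCM with environment-specific loadings.

    Structural equations per environment ``(gamma1, gamma2, gamma3, mu)``::

        U1 = eps_U1;  U2 = eps_U2
        X1 = gamma1*U1 + eps_X1;  X2 = gamma2*U2 + eps_X2;  X3 = gamma3*U1 + eps_X3
        T  ~ policy(X)            (default: the logistic logging policy)
        Y  = T*(1 + 0.5*X2 + 0.5*U1) + main_effect(variant) + eps_Y

    Only ``{x2}`` is effect-invariant: the CATE given ``x2`` equals
    ``1 + 0.5 x2`` (or ``1 + 0.5 x2^2 + 0.5 x2^3`` for the nonlinear-CATE
    variant) in every environment, while conditioning on ``x1`` or ``x3``
    leaks the environment-specific loading on ``U1``.
    """
    if variant not in EXAMPLE1_VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; choose from {EXAMPLE1_VARIANTS}")
    if n_per_env < 0:
        raise ConfigError("n_per_env must be nonnegative")
    params = [_as_param_tuple(p) for p in env_params]
    if not params:
        raise ConfigError("need at least one environment")
    if policy is None:
        policy = make_default_training_policy()
    rng = np.random.default_rng(seed)
    rows, lat = [], []
    for e, (g1, g2, g3, mu) in enumerate(params):
        u1 = rng.standard_normal(n_per_env)
        u2 = rng.standard_normal(n_per_env)
        x1 = g1 * u1 + rng.standard_normal(n_per_env)
        x2 = g2 * u2 + rng.standard_normal(n_per_env)
        x3 = g3 * u1 + rng.standard_normal(n_per_env)
        x_df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        t, prop = _sample_actions(policy, x_df, rng)
        if variant == "linear":
            effect = 1.0 + 0.5 * x2 + 0.5 * u1
            main = u1 + u2 + x2 + x3 + mu
        elif variant == "nonlinear_main":
            effect = 1.0 + 0.5 * x2 + 0.5 * u1
            main = u1 + x2 + mu + u2 - 0.5 * x2 * x3 + x3
        else:  # nonlinear_cate
            effect = 1.0 + 0.5 * x2 ** 2 + 0.5 * x2 ** 3 + 0.5 * u1
            main = u1 + x2 + mu + u2 - 0.5 * x2 * x3 + x3
        y = t * effect + main + rng.standard_normal(n_per_env)
        rows.append(pd.DataFrame({"y": y, "t": t, "env": e, "prop": prop,
                                  "x1": x1, "x2": x2, "x3": x3}))
        lat.append(pd.DataFrame({"u1": u1, "u2": u2}))
    frame = pd.concat(rows, ignore_index=True)
    return SimOutput(data=MultiEnvDataset.from_frame(frame),
                     latent=pd.concat(lat, ignore_index=True),
                     truth=example1_truth(variant), truth_subset=("x2",))


# ---------------------------------------------------------------------------
# Micro-randomized-trial-like fixture
# ---------------------------------------------------------------------------

#: Treatment-effect ("f") feature names of the MRT fixture.
MRT_EFFECT_FEATURES = ("decision_bucket", "engagement", "location", "variation")
#: Baseline-only features appended to the f-features in the main effect.
MRT_BASELINE_FEATURES = ("prior_steps", "prev_day_steps", "temperature")


@dataclass
class MRTCoefConfig:
    """Distributions of the per-user outcome-model coefficients.

    ``beta_mean``/``beta_sd`` parameterize the treatment-effect coefficients
    ``beta_u`` (intercept first, then one entry per f-feature); features named
    in ``invariant_features`` (``"intercept"`` allowed) keep their coefficient
    constant across users, making every subset of those features e-invariant
    in truth.  ``alpha_*`` parameterize the baseline ``alpha_u`` (intercept +
    f-features + baseline-only features).
    """

    beta_mean: tuple = (0.3, 0.15, -0.3, 0.1, 0.2)
    beta_sd: tuple = (0.15, 0.1, 0.25, 0.1, 0.1)
    alpha_mean: tuple = (1.0, 0.1, 0.2, -0.1, 0.1, 0.4, 0.2, -0.1)
    alpha_sd: float = 0.3
    invariant_features: tuple = ("intercept", "decision_bucket", "location",
                                 "variation")
    noise_sd: float = 1.0
    rand_prob: float = 0.6

    def __post_init__(self) -> None:
        k = 1 + len(MRT_EFFECT_FEATURES)
        if len(self.beta_mean) != k or len(self.beta_sd) != k:
            raise ConfigError(f"beta_mean/beta_sd must have length {k}")
        if len(self.alpha_mean) != 1 + len(MRT_EFFECT_FEATURES) + len(MRT_BASELINE_FEATURES):
            raise ConfigError("alpha_mean has the wrong length")
        valid = ("intercept",) + MRT_EFFECT_FEATURES
        bad = [f for f in self.invariant_features if f not in valid]
        if bad:
            raise ConfigError(f"unknown invariant feature(s) {bad}")
        if not 0.0 < self.rand_prob < 1.0:
            raise ConfigError("rand_prob must lie in (0, 1)")


def simulate_mrt_fixture(n_users: int, traj_len: int,
                         coef_config: MRTCoefConfig | None = None,
                         seed: int = 0) -> SimOutput:
    """Micro-randomized-trial-like data: users as environments.

    Per decision point the fixture draws a bucketized decision time (0-4), a
    binary engagement indicator, a 3-level location code and a binary
    step-count-variation indicator (the treatment-effect features), plus three
    continuous baseline-only features.  The outcome is linear,
    ``y = alpha_u' g(x) + beta_u' f(x) * t + eps``, with user-specific
    coefficients drawn from ``coef_config`` and a Bernoulli randomization of
    the binary "deliver suggestion" treatment.
    """
    if n_users < 2:
        raise ConfigError("need at least 2 users (environments)")
    if traj_len < 1:
        raise ConfigError("traj_len must be positive")
    cfg = coef_config or MRTCoefConfig()
    rng = np.random.default_rng(seed)
    beta_names = ("intercept",) + MRT_EFFECT_FEATURES
    beta_mean = np.asarray(cfg.beta_mean, dtype=float)
    beta_sd = np.array([0.0 if name in cfg.invariant_features else sd
                        for name, sd in zip(beta_names, cfg.beta_sd)])
    alpha_mean = np.asarray(cfg.alpha_mean, dtype=float)

    rows = []
    truth_per_env: dict = {}
    betas = beta_mean + beta_sd * rng.standard_normal((n_users, len(beta_mean)))
    alphas = alpha_mean + cfg.alpha_sd * rng.standard_normal(
        (n_users, len(alpha_mean)))
    for u in range(n_users):
        db = rng.integers(0, 5, traj_len).astype(float)
        eng = rng.integers(0, 2, traj_len).astype(float)
        loc = rng.integers(0, 3, traj_len).astype(float)
        var = rng.integers(0, 2, traj_len).astype(float)
        base = rng.standard_normal((traj_len, len(MRT_BASELINE_FEATURES)))
        f_mat = np.column_stack([np.ones(traj_len), db, eng, loc, var])
        g_mat = np.column_stack([f_mat, base])
        t = (rng.random(traj_len) < cfg.rand_prob).astype(int)
        prop = np.where(t == 1, cfg.rand_prob, 1.0 - cfg.rand_prob)
        y = g_mat @ alphas[u] + (f_mat @ betas[u]) * t \
            + cfg.noise_sd * rng.standard_normal(traj_len)
        row = pd.DataFrame({"y": y, "t": t, "env": u, "prop": prop,
                            "decision_bucket": db, "engagement": eng,
                            "location": loc, "variation": var})
        for j, name in enumerate(MRT_BASELINE_FEATURES):
            row[name] = base[:, j]
        rows.append(row)
        beta_u = betas[u]

        def user_truth(xs, t_arm, _b=beta_u):
            f = np.column_stack([np.ones(len(xs)), xs])
            return f @ _b

        truth_per_env[u] = CATEFunction(subset=MRT_EFFECT_FEATURES,
                                        fn=user_truth)

    frame = pd.concat(rows, ignore_index=True)
    mean_truth = CATEFunction(
        subset=MRT_EFFECT_FEATURES,
        fn=lambda xs, t_arm: np.column_stack(
            [np.ones(len(xs)), xs]) @ beta_mean)
    return SimOutput(data=MultiEnvDataset.from_frame(frame),
                     latent=pd.DataFrame(
                         {"user_beta_row": np.repeat(np.arange(n_users),
                                                     traj_len)}),
                     truth=mean_truth, truth_subset=MRT_EFFECT_FEATURES,
                     truth_per_env=truth_per_env)
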