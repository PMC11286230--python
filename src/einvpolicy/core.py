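"""Shared domain types for multi-environment policy learning.

This module houses the basic objects used throughout the package:

* :class:`TreatmentSpace` -- a finite treatment set with a designated baseline.
* :class:`MultiEnvDataset` -- one record per decision: outcome ``y``, treatment
  ``t``, environment label ``env``, covariates ``x`` and the recorded action
  probability ``prop`` of the logging policy.
* :class:`Policy` -- a map from covariates to a probability vector over
  treatments, optionally restricted to a covariate subset.
* :class:`CATEFunction` -- a conditional average treatment effect (CATE)
  relative to the baseline arm, defined on a covariate subset.
* :class:`SubsetTestResult` -- the outcome of a per-subset invariance test.

plus the doubly robust (DR) pseudo-outcome transformation and a pooled CATE
estimator built on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LinearRegression

#: Logging propensities below this bound violate strict positivity.
MIN_PROPENSITY = 1e-6

#: Absolute tolerance used when detecting ties between treatment-arm effects.
TIE_ATOL = 1e-12


class PositivityError(ValueError):
    """A recorded or modelled action probability violates strict positivity."""


class DegenerateDesignError(ValueError):
    """A regression design is rank deficient or an arm/stratum is empty."""


class ConfigError(ValueError):
    """Invalid configuration of a simulator, test or learner."""


class UnsupportedTreatmentError(ValueError):
    """An operation requiring a binary treatment received more levels."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreatmentSpace:
    """A finite set of ``k`` treatment levels ``{0, ..., k-1}`` with baseline ``t0``."""

    k: int = 2
    t0: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError(f"need at least 2 treatment levels, got k={self.k}")
        if not 0 <= self.t0 < self.k:
            raise ConfigError(f"baseline t0={self.t0} outside {{0,...,{self.k - 1}}}")


@dataclass
class MultiEnvDataset:
    """Logged multi-environment bandit data, one record per decision.

    Parameters
    ----------
    y
        Real-valued outcome per record.
    x
        Covariates as an ``n x d`` DataFrame with named columns.
    t
        Treatment index per record (integer in ``{0, ..., k-1}``).
    env
        Environment label per record (any hashable; users, sites, regimes).
    prop
        Probability the logging policy assigned to the *realized* action,
        ``pi_i(t_i | x_i)``; must be strictly positive (overlap).
    """

    y: np.ndarray
    x: pd.DataFrame
    t: np.ndarray
    env: np.ndarray
    prop: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = pd.DataFrame(self.x).reset_index(drop=True)
        self.t = np.asarray(self.t, dtype=int)
        self.env = np.asarray(self.env)
        self.prop = np.asarray(self.prop, dtype=float)
        n = len(self.y)
        for name, arr in (("x", self.x), ("t", self.t), ("env", self.env),
                          ("prop", self.prop)):
            if len(arr) != n:
                raise ConfigError(f"column '{name}' has length {len(arr)} != n={n}")
        if n and (np.any(~np.isfinite(self.y)) or self.x.isna().any().any()):
            raise ConfigError("records with missing fields are rejected, not imputed")
        if n and np.any(self.prop < MIN_PROPENSITY):
            raise PositivityError(
                f"recorded action probabilities must be >= {MIN_PROPENSITY}")
        if n and np.any(self.prop > 1.0 + 1e-12):
            raise PositivityError("recorded action probabilities must be <= 1")

    # -- basic accessors ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.x.columns)

    @property
    def environments(self) -> list:
        """Distinct environment labels in sorted order."""
        return sorted(pd.unique(self.env).tolist())

    @property
    def n_treatments(self) -> int:
        return int(self.t.max()) + 1 if self.n else 2

    def n_per_env(self) -> dict:
        vals, counts = np.unique(self.env, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset_rows(self, idx: np.ndarray) -> "MultiEnvDataset":
        idx = np.asarray(idx)
        return MultiEnvDataset(
            y=self.y[idx], x=self.x.iloc[idx], t=self.t[idx],
            env=self.env[idx], prop=self.prop[idx])

    def xs(self, subset: Sequence[str]) -> np.ndarray:
        """Covariate matrix restricted to a (possibly empty) named subset."""
        subset = list(subset)
        if not subset:
            return np.empty((self.n, 0))
        missing = [c for c in subset if c not in self.x.columns]
        if missing:
            raise ConfigError(f"unknown covariates {missing}")
        return self.x[subset].to_numpy(dtype=float)

    def propensity_of_treat(self) -> np.ndarray:
        """Recover ``pi(1 | x_i)`` from the recorded realized-action probability.

        Only valid for binary treatments, where ``prop`` determines both arms.
        """
        if self.n and self.t.max() > 1:
            raise UnsupportedTreatmentError(
                "propensity recovery from `prop` requires a binary treatment")
        return np.where(self.t == 1, self.prop, 1.0 - self.prop)

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"y": self.y, "t": self.t, "env": self.env,
                            "prop": self.prop})
        return pd.concat([out, self.x.reset_index(drop=True)], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MultiEnvDataset":
        required = ["y", "t", "env", "prop"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ConfigError(f"missing required column(s) {missing}")
        cov = [c for c in df.columns if c not in required]
        return cls(y=df["y"].to_numpy(float), x=df[cov].copy(),
                   t=df["t"].to_numpy(int), env=df["env"].to_numpy(),
                   prop=df["prop"].to_numpy(float))


@dataclass
class Policy:
    """A (possibly covariate-subset-restricted) randomized treatment policy.

    ``prob_fn`` maps an ``n x d`` covariate DataFrame to an ``n x k`` matrix of
    action probabilities.  When ``support_subset`` is set, the policy's output
    may depend only on those covariates.
    """

    prob_fn: Callable[[pd.DataFrame], np.ndarray]
    k: int = 2
    support_subset: tuple[str, ...] | None = None
    name: str = "policy"

    def prob_matrix(self, x: pd.DataFrame) -> np.ndarray:
        p = np.asarray(self.prob_fn(pd.DataFrame(x)), dtype=float)
        if p.ndim == 1:
            p = np.column_stack([1.0 - p, p])
        if p.shape[1] != self.k:
            raise ConfigError(f"policy emitted {p.shape[1]} columns, expected {self.k}")
        if np.any(p < -1e-12) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-12):
            raise ConfigError("policy output is not a probability vector")
        return np.clip(p, 0.0, 1.0)

    def action_prob(self, x: Mapping[str, float] | pd.Series) -> np.ndarray:
        """Probability vector for a single covariate vector."""
        row = pd.DataFrame([dict(x)]) if not isinstance(x, pd.Series) \
            else x.to_frame().T
        return self.prob_matrix(row)[0]

    def sample(self, x: pd.DataFrame, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw one action per row; returns (actions, realized-action probs)."""
        p = self.prob_matrix(x)
        u = rng.random(len(p))
        cum = np.cumsum(p, axis=1)
        a = (u[:, None] >= cum).sum(axis=1)
        return a, p[np.arange(len(p)), a]


def make_constant_policy(t: int, space: TreatmentSpace = TreatmentSpace()) -> Policy:
    """The deterministic policy that always selects treatment ``t``."""
    if not 0 <= t < space.k:
        raise ConfigError(f"treatment {t} outside the treatment space")
    vec = np.eye(space.k)[t]

    def fn(x: pd.DataFrame) -> np.ndarray:
        return np.tile(vec, (len(x), 1))

    return Policy(fn, k=space.k, support_subset=(), name=f"constant[{t}]")


def make_bernoulli_policy(q: float) -> Policy:
    """Context-free binary policy selecting treatment 1 with probability ``q``."""
    if not 0.0 < q < 1.0:
        raise ConfigError(f"q={q} must lie strictly in (0, 1)")

    def fn(x: pd.DataFrame) -> np.ndarray:
        return np.tile([1.0 - q, q], (len(x), 1))

    return Policy(fn, k=2, support_subset=(), name=f"bernoulli[{q}]")


@dataclass
class CATEFunction:
    """Treatment effect ``tau(x_S, t)`` relative to the baseline arm.

    ``fn(xs, t)`` receives an ``n x |S|`` array of subset covariates and a
    non-baseline treatment index; the baseline arm evaluates to exactly zero.
    """

    subset: tuple[str, ...]
    fn: Callable[[np.ndarray, int], np.ndarray]
    space: TreatmentSpace = field(default_factory=TreatmentSpace)

    def __call__(self, xs: np.ndarray | pd.DataFrame, t: int) -> np.ndarray:
        if isinstance(xs, pd.DataFrame):
            xs = xs[list(self.subset)].to_numpy(float) if self.subset \
                else np.empty((len(xs), 0))
        xs = np.atleast_2d(np.asarray(xs, dtype=float))
        if xs.shape[1] != len(self.subset):
            raise ConfigError(
                f"expected {len(self.subset)} subset columns, got {xs.shape[1]}")
        if t == self.space.t0:
            return np.zeros(len(xs))
        return np.asarray(self.fn(xs, t), dtype=float).reshape(len(xs))


@dataclass(frozen=True)
class SubsetTestResult:
    """Outcome of an e-invariance test for one covariate subset."""

    subset: tuple[str, ...]
    method: str
    statistic: float
    df: int
    p_value: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ConfigError(f"p-value {self.p_value} outside [0, 1]")
        if self.df < 1:
            raise ConfigError("degrees of freedom must be positive")

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {"subset": list(self.subset), "method": self.method,
                "statistic": float(self.statistic), "df": int(self.df),
                "p_value": float(self.p_value), "alpha": float(self.alpha),
                "reject": bool(self.reject)}


# ---------------------------------------------------------------------------
# Doubly robust pseudo-outcomes
# ---------------------------------------------------------------------------

def pseudo_outcome(y: float, x, t: int, mu_bar, pi_bar, env) -> float:
    """DR pseudo-outcome for a single binary-treatment record.

    ``mu_bar`` is either a callable ``(x, t) -> float`` or a mapping from
    environment label to such a callable; ``pi_bar`` is a callable
    ``(t, x) -> float`` modelling the logging policy.  Returns::

        mu(x,1) - mu(x,0) + 1{t=1}(y - mu(x,1))/pi(1|x)
                          - 1{t=0}(y - mu(x,0))/(1 - pi(1|x))

    whose conditional mean given any covariate subset equals the CATE whenever
    at least one of the two nuisance models is correct (double robustness).
    """
    if t not in (0, 1):
        raise UnsupportedTreatmentError(
            "pseudo-outcomes are defined for binary treatments with t0=0; "
            "multi-level treatments are handled by per-level reduction")
    mu = mu_bar[env] if isinstance(mu_bar, Mapping) else mu_bar
    p1 = float(pi_bar(1, x))
    taken = p1 if t == 1 else 1.0 - p1
    if taken < MIN_PROPENSITY:
        raise PositivityError(
            f"modelled propensity {taken} of the logged action below the "
            "positivity floor")
    m1, m0 = float(mu(x, 1)), float(mu(x, 0))
    out = m1 - m0
    if t == 1:
        out += (y - m1) / p1
    else:
        out -= (y - m0) / (1.0 - p1)
    return out


def pseudo_outcomes(data: MultiEnvDataset,
                    mu_models: Mapping,
                    pi_treat: np.ndarray) -> np.ndarray:
    """Vectorized DR pseudo-outcomes for a binary-treatment dataset.

    ``mu_models[e]`` must be a callable ``(x_df, t) -> array``; ``pi_treat``
    holds the modelled ``pi(1 | x_i)`` per record.
    """
    pi_treat = np.asarray(pi_treat, dtype=float)
    # positivity is only needed for the probability of the action actually
    # taken (the only quantity divided by); the complement may underflow to
    # 0/1 in float for extreme covariates without affecting the estimator
    taken = np.where(data.t == 1, pi_treat, 1.0 - pi_treat)
    if np.any(taken < MIN_PROPENSITY):
        raise PositivityError(
            "modelled propensity of the logged action below the positivity floor")
    if data.n and data.t.max() > 1:
        raise UnsupportedTreatmentError("pseudo-outcomes require a binary treatment")
    m1 = np.empty(data.n)
    m0 = np.empty(data.n)
    for e in data.environments:
        mask = data.env == e
        mu = mu_models[e]
        xe = data.x.loc[mask]
        m1[mask] = mu(xe, 1)
        m0[mask] = mu(xe, 0)
    treated = data.t == 1
    o = m1 - m0
    o[treated] += (data.y[treated] - m1[treated]) / pi_treat[treated]
    o[~treated] -= (data.y[~treated] - m0[~treated]) / (1.0 - pi_treat[~treated])
    return o


# ---------------------------------------------------------------------------
# Stratified splitting and nuisance fitting (shared with the DR test)
# ---------------------------------------------------------------------------

def stratified_split_indices(data: MultiEnvDataset, fraction: float,
                             seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint exhaustive split, stratified by environment x treatment arm."""
    if not 0.0 < fraction < 1.0:
        raise ConfigError(f"split fraction {fraction} outside (0, 1)")
    rng = np.random.default_rng(seed)
    first: list[np.ndarray] = []
    second: list[np.ndarray] = []
    for e in data.environments:
        for arm in np.unique(data.t):
            idx = np.flatnonzero((data.env == e) & (data.t == arm))
            if len(idx) < 2:
                raise ConfigError(
                    f"environment {e!r}, arm {arm} has {len(idx)} record(s); "
                    "need at least 2 per stratum to split")
            idx = rng.permutation(idx)
            cut = int(round(fraction * len(idx)))
            cut = min(max(cut, 1), len(idx) - 1)
            first.append(idx[:cut])
            second.append(idx[cut:])
    return np.sort(np.concatenate(first)), np.sort(np.concatenate(second))


def fit_mu_models(data: MultiEnvDataset, learner=None) -> dict:
    """Per-environment outcome regressions ``mu_e(x, t)``.

    A separate clone of ``learner`` (default: ordinary least squares) is fit
    per environment and treatment arm, which accommodates arbitrary
    treatment-covariate interactions within the learner's class.
    """
    if learner is None:
        learner = LinearRegression()
    models: dict = {}
    for e in data.environments:
        mask = data.env == e
        per_arm = {}
        for arm in (0, 1):
            sel = mask & (data.t == arm)
            if not sel.any():
                raise DegenerateDesignError(
                    f"environment {e!r} has no records in arm {arm}")
            m = clone(learner)
            m.fit(data.x.loc[sel].to_numpy(float), data.y[sel])
            per_arm[arm] = m

        def mu(x_df, t, _per_arm=per_arm):
            return _per_arm[t].predict(np.asarray(x_df, dtype=float))

        models[e] = mu
    return models


# ---------------------------------------------------------------------------
# Pooled CATE estimation
# ---------------------------------------------------------------------------

def pooled_cate_fit(data: MultiEnvDataset, subset: Sequence[str],
                    learner=None, nuisance_learner=None,
                    seed: int = 0) -> CATEFunction:
    """Pooled CATE estimate ``tau_S`` across all training environments.

    Nuisance models for each record are fit on the held-out half of a seeded
    split (stratified by environment and arm), i.e. cross-fitting over the two
    halves; DR pseudo-outcomes are formed for every record and regressed on
    the subset covariates with ``learner`` (default ordinary least squares).
    Logging propensities are taken from the recorded ``prop`` column.  The
    baseline arm evaluates to exactly zero.
    """
    subset = tuple(subset)
    if data.n == 0 or len(np.unique(data.t)) < 2:
        raise DegenerateDesignError("pooled CATE fit needs records in both arms")
    d1_idx, d2_idx = stratified_split_indices(data, 0.5, seed)
    halves = (data.subset_rows(d1_idx), data.subset_rows(d2_idx))
    o_parts, xs_parts = [], []
    for fit_half, eval_half in (halves, halves[::-1]):
        mu_models = fit_mu_models(fit_half, nuisance_learner)
        o_parts.append(pseudo_outcomes(eval_half, mu_models,
                                       eval_half.propensity_of_treat()))
        xs_parts.append(eval_half.xs(subset))
    o = np.concatenate(o_parts)
    xs = np.vstack(xs_parts)
    if xs.shape[1] == 0:
        const = float(np.mean(o))

        def fn(x_arr, t, _c=const):
            return np.full(len(np.atleast_2d(x_arr)), _c)
    else:
        model = clone(learner) if learner is not None else LinearRegression()
        model.fit(xs, o)

        def fn(x_arr, t, _m=model):
            return _m.predict(np.asarray(x_arr, dtype=float))

    return CATEFunction(subset=subset, fn=fn)


def argmax_policy_probs(effects: np.ndarray, atol: float = TIE_ATOL) -> np.ndarray:
    """Uniform distribution over the arms attaining the maximal effect.

    ``effects`` is ``n x k`` (baseline column included, typically zeros).
    Ties within ``atol`` of the row maximum share the mass equally.
    """
    effects = np.atleast_2d(np.asarray(effects, dtype=float))
    best = effects.max(axis=1, keepdims=True)
    is_best = np.abs(effects - best) <= atol
    return is_best / is_best.sum(axis=1, keepdims=True)
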