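"""Command-line interface, file I/O and experiment harness.

The CSV dialect for multi-environment logs requires the columns ``y``
(float outcome), ``t`` (integer treatment), ``env`` (environment label),
``prop`` (recorded action probability) and one column per covariate, with a
header row and no index column.  Results are written as JSON or CSV, and
every CLI run drops a ``<out>.manifest.json`` recording the configuration,
seeds and package version needed to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ConfigError, MultiEnvDataset
from .dr_test import DRTestConfig, dr_einv_test
from .evaluate import LOEOConfig, leave_one_env_out
from .few_shot import few_shot_fit
from .simulate import (draw_env_params, simulate_example1, simulate_intro,
                       simulate_mrt_fixture)
from .wald_test import wald_einv_test
from .zero_shot import ZeroShotConfig, learn_einv_policy

log = logging.getLogger("einvpolicy")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_dataset(path) -> MultiEnvDataset:
    """Read a multi-environment log CSV, reporting malformed rows by line number."""
    df = pd.read_csv(path)
    required = ["y", "t", "env", "prop"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing required column(s) {missing}")
    bad = df.index[df.drop(columns=["env"]).isna().any(axis=1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header row, 1-based
        raise ConfigError(f"{path}: malformed row(s) at line(s) {lines}")
    return MultiEnvDataset.from_frame(df)


def write_results(obj, path) -> None:
    """Write a result object to disk: DataFrames as CSV, mappings as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"cannot serialize {type(o)}")


def _write_manifest(out_path, config: dict) -> None:
    manifest = {"package_version": __version__, "config": config,
                "argv": sys.argv[1:]}
    write_results(manifest, str(out_path) + ".manifest.json")


# ---------------------------------------------------------------------------
# Rejection-rate experiment harness
# ---------------------------------------------------------------------------

def rejection_rate(variant: str, method: str, subset, n: int, n_reps: int,
                   alpha: float = 0.05, seed: int = 0,
                   dr_config: DRTestConfig | None = None,
                   env_params=None, n_env: int = 2) -> tuple[float, float]:
    """Empirical rejection rate (and its binomial SE) over seeded replicates.

    The experiment draws one set of Uniform[-3, 3] environment parameters
    from ``seed`` (unless ``env_params`` is given) and holds it fixed; each
    replicate then simulates a fresh dataset of ``n`` records under the
    logistic logging policy and runs the requested e-invariance test.
    """
    rng = np.random.default_rng(seed)
    params = env_params if env_params is not None \
        else draw_env_params(n_env, int(rng.integers(2**31 - 1)))
    sub_seeds = rng.integers(0, 2**31 - 1, size=(n_reps, 2))
    rejections = 0
    for r in range(n_reps):
        sim = simulate_example1(params, n // len(params), variant=variant,
                                seed=int(sub_seeds[r, 1]))
        if method == "wald":
            res = wald_einv_test(sim.data, subset, alpha=alpha)
        elif method == "dr":
            cfg = dataclasses.replace(dr_config or DRTestConfig(),
                                      seed=int(sub_seeds[r, 1]))
            res = dr_einv_test(sim.data, subset, alpha=alpha, config=cfg)
        else:
            raise ConfigError(f"unknown method {method!r}")
        rejections += int(res.reject)
    rate = rejections / n_reps
    se = float(np.sqrt(rate * (1 - rate) / n_reps))
    return rate, se


def run_figure2_experiment(config: dict) -> pd.DataFrame:
    """Rejection-rate table across variants, methods, subsets and sample sizes."""
    variants = config.get("variants", ["linear", "nonlinear_main",
                                       "nonlinear_cate"])
    methods = config.get("methods", ["wald", "dr"])
    subsets = [tuple(s) for s in config.get(
        "subsets", [["x1"], ["x2"], ["x3"]])]
    sample_sizes = config.get("sample_sizes", [1000, 2000, 4000, 8000])
    alpha = config.get("alpha", 0.05)
    seed = config.get("seed", 0)
    reps = {"wald": config.get("n_reps_wald", 500),
            "dr": config.get("n_reps_dr", 200)}
    rows = []
    for variant in variants:
        for method in methods:
            for subset in subsets:
                for n in sample_sizes:
                    log.info("figure2: %s/%s subset=%s n=%d", variant, method,
                             subset, n)
                    rate, se = rejection_rate(variant, method, subset, n,
                                              reps[method], alpha, seed)
                    rows.append({"variant": variant, "method": method,
                                 "subset": ",".join(subset), "n": n,
                                 "rejection_rate": rate, "binomial_se": se,
                                 "n_reps": reps[method], "alpha": alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("--verbose", is_flag=True, help="Enable DEBUG logging.")
def cli(verbose: bool) -> None:
    """Effect-invariance testing and policy learning."""
    logging.basicConfig(level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command("simulate")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def simulate_cmd(config_path: str, out: str) -> None:
    """Generate a dataset from a YAML/JSON simulator config."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    name = cfg.get("name")
    seed = int(cfg.get("seed", 0))
    if name == "intro":
        sim = simulate_intro(cfg["environments"], int(cfg["n_per_env"]),
                             seed=seed)
    elif name == "example1":
        params = cfg.get("env_params") or draw_env_params(
            int(cfg.get("n_env", 2)), seed)
        sim = simulate_example1(params, int(cfg["n_per_env"]),
                                variant=cfg.get("variant", "linear"), seed=seed)
        cfg["env_params_used"] = [list(p) for p in params]
    elif name == "mrt":
        sim = simulate_mrt_fixture(int(cfg["n_users"]), int(cfg["traj_len"]),
                                   seed=seed)
    else:
        raise ConfigError(f"unknown simulator {name!r}")
    sim.data.to_frame().to_csv(out, index=False)
    write_results({"truth_subset": list(sim.truth_subset), "config": cfg},
                  str(out) + ".truth.json")
    _write_manifest(out, cfg)
    log.info("wrote %d records to %s", sim.data.n, out)


@cli.command("test-einv")
@click.option("--data", "data_path", required=True, type=click.Path(exists=True))
@click.option("--subset", required=True,
              help="Comma-separated covariate names; empty string for the empty set.")
@click.option("--method", type=click.Choice(["wald", "dr"]), default="wald")
@click.option("--alpha", type=float, default=0.05)
@click.option("--seed", type=int, default=0)
@click.option("--out", required=True, type=click.Path())
def test_einv_cmd(data_path: str, subset: str, method: str, alpha: float,
                  seed: int, out: str) -> None:
    """Run one e-invariance test for a covariate subset."""
    data = read_dataset(data_path)
    names = tuple(s for s in subset.split(",") if s)
    if method == "wald":
        res = wald_einv_test(data, names, alpha=alpha)
    else:
        res = dr_einv_test(data, names, alpha=alpha,
                           config=DRTestConfig(seed=seed))
    write_results(res.to_dict(), out)
    _write_manifest(out, {"data": data_path, "subset": list(names),
                          "method": method, "alpha": alpha, "seed": seed})
    log.info("subset=%s p=%.4g reject=%s", names, res.p_value, res.reject)


@cli.command("learn-policy")
@click.option("--train", "train_path", required=True, type=click.Path(exists=True))
@click.option("--test-x", "test_x_path", required=True, type=click.Path(exists=True))
@click.option("--alpha", type=float, default=0.05)
@click.option("--method", type=click.Choice(["wald", "dr"]), default="wald")
@click.option("--seed", type=int, default=0)
@click.option("--out", required=True, type=click.Path())
def learn_policy_cmd(train_path: str, test_x_path: str, alpha: float,
                     method: str, seed: int, out: str) -> None:
    """Zero-shot policy learning from logs plus test-environment covariates."""
    train = read_dataset(train_path)
    x_test = pd.read_csv(test_x_path)
    result = learn_einv_policy(train, x_test, alpha=alpha,
                               config=ZeroShotConfig(method=method, seed=seed))
    payload = {
        "s_star": list(result.s_star) if result.s_star is not None else None,
        "fallback_used": result.fallback_used,
        "tie_rule": "uniform over argmax arms; subset ties seeded-random",
        "criterion": {",".join(s): v for s, v in result.criterion.items()},
        "tested_subsets": [r.to_dict() for r in result.collection.all_results]
        if result.collection else [],
    }
    write_results(payload, out)
    _write_manifest(out, {"train": train_path, "test_x": test_x_path,
                          "alpha": alpha, "method": method, "seed": seed})
    log.info("selected subset: %s", result.s_star)


@cli.command("fewshot")
@click.option("--train", "train_path", required=True, type=click.Path(exists=True))
@click.option("--test", "test_path", required=True, type=click.Path(exists=True))
@click.option("--alpha", type=float, default=0.05)
@click.option("--seed", type=int, default=0)
@click.option("--out", required=True, type=click.Path())
def fewshot_cmd(train_path: str, test_path: str, alpha: float, seed: int,
                out: str) -> None:
    """Few-shot constrained CATE estimation on a small labelled test sample."""
    train = read_dataset(train_path)
    test = read_dataset(test_path)
    zs = learn_einv_policy(train, test.x, alpha=alpha,
                           config=ZeroShotConfig(seed=seed))
    if zs.fallback_used:
        raise ConfigError("no e-invariant subset accepted on the training data")
    tau_tr = zs.cates[zs.s_star]
    model = few_shot_fit(test, tau_tr, seed=seed)
    # constraint diagnostic: how far the implied CATE's conditional mean
    # (smoothed on x_S) drifts from the training CATE on the test sample
    tau = model.implied_tau
    implied = tau(test.x[list(tau.subset)], 1)
    base = tau_tr(test.x, 1)
    payload = {
        "subset_S": list(model.subset_S),
        "subset_N": list(model.subset_N),
        "g_coef": model.g_coef,
        "constraint_gap_mean": float(np.mean(implied - base)),
        "policy": "argmax of implied CATE, uniform tie-breaking",
    }
    write_results(payload, out)
    _write_manifest(out, {"train": train_path, "test": test_path,
                          "alpha": alpha, "seed": seed})


@cli.command("evaluate")
@click.option("--data", "data_path", required=True, type=click.Path(exists=True))
@click.option("--features", "features_path", required=True,
              type=click.Path(exists=True))
@click.option("--alpha", type=float, default=0.05)
@click.option("--seed", type=int, default=0)
@click.option("--out", required=True, type=click.Path())
def evaluate_cmd(data_path: str, features_path: str, alpha: float, seed: int,
                 out: str) -> None:
    """Leave-one-environment-out policy comparison with residual bootstrap."""
    data = read_dataset(data_path)
    with open(features_path) as fh:
        feats = yaml.safe_load(fh)
    cfg = LOEOConfig(f_names=tuple(feats["f_names"]),
                     g_extra_names=tuple(feats.get("g_extra_names", [])),
                     alpha=alpha, seed=seed,
                     n_boot=int(feats.get("n_boot", 1000)))
    table, p_value = leave_one_env_out(data, cfg)
    table.to_csv(out, index=False)
    write_results({"signed_rank_p_value": p_value,
                   "n_environments": len(table)}, str(out) + ".summary.json")
    _write_manifest(out, {"data": data_path, "features": feats,
                          "alpha": alpha, "seed": seed})
    log.info("signed-rank p-value: %.4g", p_value)


@cli.command("figure2")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def figure2_cmd(config_path: str, out: str) -> None:
    """Rejection-rate table for the simulated testing experiment."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    table = run_figure2_experiment(cfg)
    table.to_csv(out, index=False)
    _write_manifest(out, cfg)


if __name__ == "__main__":  # pragma: no cover
    cli()
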