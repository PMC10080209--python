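"""Cross-validation planning, accuracy metrics and benchmark orchestration.

The benchmark protocol is 5 repeats of 5-fold cross-validation per
(scenario, trait replicate, method): accuracy is the Pearson correlation
between observed phenotypes and predicted genomic values of the held-out
fold, giving 25 r values per cell. Method pairs are compared with a
two-sided Wilcoxon rank-sum test, pooling accuracies across settings.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genosim import GenotypeMatrix, simulate_genotypes
from .gpmodels import (
    MCMCSettings,
    fit_bayesA,
    fit_bayesB,
    fit_boosted_trees,
    fit_gblup,
    fit_rkhs,
    fit_tree_bagging,
    gaussian_kernel,
    grm_vanraden,
    predict_bayes,
    predict_gblup,
    predict_rkhs,
    predict_trees,
)
from .gpmodels.rkhs import DEFAULT_BANDWIDTHS
from .phenosim import Scenario, simulate_phenotypes

__all__ = [
    "CVPlan",
    "make_cv_plan",
    "pearson_accuracy",
    "wilcoxon_rank_sum",
    "sem",
    "fit_predict_fold",
    "benchmark_scenario",
    "run_benchmark",
    "summarize_accuracy",
]

KNOWN_METHODS = ("gblup", "bayesA", "bayesB", "rkhs", "rf", "xgboost")


@dataclass
class CVPlan:
    """Repeated k-fold assignments: ``assignments[r, i]`` is sample i's
    fold label in repeat r."""

    n: int
    k_folds: int
    repeats: int
    assignments: np.ndarray
    seed: int | None = field(default=None, compare=False)

    def fold_indices(self, repeat: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, test) index arrays for one CV cell."""
        test = np.flatnonzero(self.assignments[repeat] == fold)
        train = np.flatnonzero(self.assignments[repeat] != fold)
        return train, test

    def iter_splits(self):
        for r in range(self.repeats):
            for f in range(self.k_folds):
                train, test = self.fold_indices(r, f)
                yield r, f, train, test


def make_cv_plan(n: int, k: int = 5, repeats: int = 5, seed: int | None = None) -> CVPlan:
    """Random unstratified repeated k-fold plan with near-equal folds."""
    if n < k or k < 2:
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    assignments = np.empty((repeats, n), dtype=np.int32)
    base, extra = divmod(n, k)
    sizes = np.array([base + (1 if f < extra else 0) for f in range(k)])
    labels = np.repeat(np.arange(k, dtype=np.int32), sizes)
    for r in range(repeats):
        perm = rng.permutation(n)
        assignments[r, perm] = labels
    return CVPlan(n=n, k_folds=k, repeats=repeats, assignments=assignments, seed=seed)


def pearson_accuracy(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Sample Pearson correlation; constant inputs give 0 with a warning."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if len(y_obs) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        warnings.warn("degenerate (constant) prediction or observation; r := 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(y_obs, y_pred)[0, 1])


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def wilcoxon_rank_sum(r_a, r_b) -> tuple[float, float]:
    """Two-sided rank-sum test on pooled midranks.

    Exact null enumeration over all rank assignments when both samples
    have at most 10 values; otherwise the normal approximation with tie
    correction and continuity correction.
    Returns (rank-sum statistic of the first sample, p-value).
    """
    a = np.asarray(r_a, dtype=float)
    b = np.asarray(r_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    mean_w = n1 * (n1 + n2 + 1) / 2.0

    if n1 <= 10 and n2 <= 10:
        dev = abs(w - mean_w)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            total += 1
            ws = ranks[list(combo)].sum()
            if abs(ws - mean_w) >= dev - 1e-9:
                count += 1
        return w, count / total

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return w, 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    return w, float(2.0 * stats.norm.sf(z))


def sem(values) -> float:
    """Standard error of the mean: sample SD / sqrt(count)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    return float(v.std(ddof=1) / math.sqrt(v.size))


# ---------------------------------------------------------------------------
# method adapters


def _default_options() -> dict:
    return {
        "mcmc": MCMCSettings(),
        "bandwidths": DEFAULT_BANDWIDTHS,
        "rf_grid": None,
        "xgb_grid": None,
        "rf_n_trees": 500,
        "xgb_n_trees": 100,
        "pi": 0.5,
        "fixed": None,  # full-length covariate matrix, sliced per fold
    }


def _precompute(method: str, G: GenotypeMatrix, cache: dict, options: dict):
    if method == "gblup" and "grm" not in cache:
        cache["grm"] = grm_vanraden(G).matrix
    if method == "rkhs" and "kernels" not in cache:
        cache["kernels"] = [gaussian_kernel(G, b).matrix for b in options["bandwidths"]]
    if method in ("bayesA", "bayesB", "rf", "xgboost") and "X" not in cache:
        cache["X"] = G.dosages.astype(np.float64)


def fit_predict_fold(
    method: str,
    G: GenotypeMatrix,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    seed: int = 0,
    options: dict | None = None,
    cache: dict | None = None,
) -> np.ndarray:
    """Fit one method on the training fold and predict the held-out fold.

    ``cache`` (per genotype matrix) avoids recomputing kinships across
    folds; pass the same dict for every fold of a benchmark run.
    """
    if method not in KNOWN_METHODS:
        raise ValueError(f"unknown method {method!r}")
    opts = {**_default_options(), **(options or {})}
    cache = cache if cache is not None else {}
    _precompute(method, G, cache, opts)
    y = np.asarray(y, dtype=float)
    fixed = opts["fixed"]
    f_tr = fixed[train] if fixed is not None else None
    f_te = fixed[test] if fixed is not None else None

    if method == "gblup":
        K = cache["grm"]
        model = fit_gblup(y[train], K[np.ix_(train, train)], fixed=f_tr)
        return predict_gblup(model, K[np.ix_(test, train)], fixed=f_te)
    if method == "rkhs":
        kernels = cache["kernels"]
        mcmc = _reseed(opts["mcmc"], seed)
        model = fit_rkhs(
            y[train],
            [K[np.ix_(train, train)] for K in kernels],
            settings=mcmc,
            fixed=f_tr,
        )
        return predict_rkhs(model, [K[np.ix_(test, train)] for K in kernels], fixed=f_te)
    X = cache["X"]
    if method == "bayesA":
        model = fit_bayesA(X[train], y[train], settings=_reseed(opts["mcmc"], seed), fixed=f_tr)
        return predict_bayes(model, X[test], fixed=f_te)
    if method == "bayesB":
        model = fit_bayesB(
            X[train], y[train], settings=_reseed(opts["mcmc"], seed), pi=opts["pi"], fixed=f_tr
        )
        return predict_bayes(model, X[test], fixed=f_te)
    if method == "rf":
        model = fit_tree_bagging(
            X[train], y[train], grid=opts["rf_grid"], seed=seed, fixed=f_tr,
            n_trees=opts["rf_n_trees"],
        )
        return predict_trees(model, X[test], fixed=f_te)
    # xgboost
    model = fit_boosted_trees(
        X[train], y[train], grid=opts["xgb_grid"], seed=seed, fixed=f_tr,
        n_trees=opts["xgb_n_trees"],
    )
    return predict_trees(model, X[test], fixed=f_te)


def _reseed(settings: MCMCSettings, seed: int) -> MCMCSettings:
    return MCMCSettings(
        n_iter=settings.n_iter,
        burn_in=settings.burn_in,
        thin=settings.thin,
        seed=seed,
        prior_df=settings.prior_df,
        prior_R2=settings.prior_R2,
    )


def benchmark_scenario(
    G: GenotypeMatrix,
    phenotypes: np.ndarray,
    methods,
    scenario_id: str = "scenario",
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    options: dict | None = None,
    max_failure_rate: float = 0.2,
) -> pd.DataFrame:
    """Run repeated k-fold CV of every method on each trait column.

    ``phenotypes`` is (n,) or (n, n_traits). Returns the tidy accuracy
    table with one row per (trait, method, repeat, fold). Fold-level fit
    failures are recorded as NaN; more than ``max_failure_rate`` of cells
    failing aborts the run.
    """
    Y = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    if Y.shape[0] != G.n_samples:
        Y = Y.T
    plan = make_cv_plan(G.n_samples, k=k, repeats=repeats, seed=seed)
    cache: dict = {}
    records = []
    failures = 0
    total = 0
    for t in range(Y.shape[1]):
        y = Y[:, t]
        for method in methods:
            for r, f, train, test in plan.iter_splits():
                total += 1
                fold_seed = (seed * 1_000_003 + t * 10_007 + r * 101 + f) & 0x7FFFFFFF
                try:
                    pred = fit_predict_fold(method, G, y, train, test, fold_seed, options, cache)
                    acc = pearson_accuracy(y[test], pred)
                except Exception as exc:  # noqa: BLE001 - per-cell isolation
                    warnings.warn(
                        f"fit failed for method={method} trait={t} repeat={r} fold={f}: {exc}",
                        stacklevel=2,
                    )
                    acc = np.nan
                    failures += 1
                    if failures > max_failure_rate * max(total, 25):
                        raise RuntimeError(
                            f"{failures}/{total} fold fits failed; aborting benchmark"
                        ) from exc
                records.append(
                    {
                        "scenario_id": scenario_id,
                        "trait": t,
                        "method": method,
                        "repeat": r,
                        "fold": f,
                        "r": acc,
                    }
                )
    return pd.DataFrame.from_records(records)


def run_benchmark(
    scenarios,
    methods,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    maf: float = 0.4,
    options: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate each scenario's data and benchmark all methods on it.

    Returns the concatenated accuracy table and a summary dict with per
    (scenario, method) means and SEMs plus pairwise Wilcoxon p-values
    pooled over scenarios.
    """
    tables = []
    root = np.random.SeedSequence(seed)
    for scen_seq, scenario in zip(root.spawn(len(scenarios)), scenarios):
        if not isinstance(scenario, Scenario):
            raise TypeError("scenarios must be Scenario instances")
        g_seed, p_seed, cv_seed = (int(s.generate_state(1)[0]) & 0x7FFFFFFF for s in scen_seq.spawn(3))
        G = simulate_genotypes(scenario.n, scenario.p, maf=maf, seed=g_seed)
        phen = simulate_phenotypes(G, scenario, seed=p_seed)
        table = benchmark_scenario(
            G,
            phen.values,
            methods,
            scenario_id=scenario.scenario_id,
            k=k,
            repeats=repeats,
            seed=cv_seed,
            options=options,
        )
        table["c"] = scenario.c
        tables.append(table)
    acc = pd.concat(tables, ignore_index=True)
    return acc, summarize_accuracy(acc)


def summarize_accuracy(acc: pd.DataFrame) -> dict:
    """Mean r and SEM per (scenario, method); pairwise pooled Wilcoxon."""
    ok = acc.dropna(subset=["r"])
    summary: dict = {"n_failures": int(acc["r"].isna().sum()), "cells": {}}
    for (sid, method), group in ok.groupby(["scenario_id", "method"]):
        vals = group["r"].to_numpy()
        summary["cells"][f"{sid}|{method}"] = {
            "mean_r": float(vals.mean()),
            "sem": sem(vals) if len(vals) >= 2 else float("nan"),
            "n": int(len(vals)),
        }
    methods = sorted(ok["method"].unique())
    pairwise = {}
    for m1, m2 in itertools.combinations(methods, 2):
        a = ok.loc[ok["method"] == m1, "r"].to_numpy()
        b = ok.loc[ok["method"] == m2, "r"].to_numpy()
        if len(a) and len(b):
            _, p = wilcoxon_rank_sum(a, b)
            pairwise[f"{m1}|{m2}"] = float(p)
    summary["wilcoxon_p"] = pairwise
    return summary
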