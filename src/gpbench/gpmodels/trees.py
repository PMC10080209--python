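"""Decision-tree ensemble regressors with inner-CV hyperparameter tuning.

Random Forest: 500 bagged trees, tuning mtry over {p/3, p/4, p/5, p/6}
(floored, deduplicated, minimum 1) and the minimum terminal node size
over {0.01, 0.05, 0.1, 0.2, 0.3} x n_train.

Boosted trees: gradient-boosted regression trees tuned over
max_depth {2, 3, 4, 50, 100, 500}, per-tree feature subsampling
{0.1, 0.2, 0.3, 0.5, 0.7, 0.9} and row subsampling {0.7, 0.8, 0.9}.
The backend is scikit-learn's GradientBoostingRegressor, which exposes
the same three knobs (max_features ~ colsample_bytree).

Candidates are ranked by mean squared error over an inner 5-fold CV on
the training data; everything is seeded for determinism. Optional fixed
covariates are appended as extra input features.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold

from .base import FittedModel, TuningGrid

__all__ = [
    "fit_tree_bagging",
    "fit_boosted_trees",
    "predict_trees",
    "default_rf_grid",
    "default_xgb_grid",
]

RF_N_TREES = 500
RF_MTRY_DIVISORS = (3, 4, 5, 6)
RF_NODESIZE_FRACTIONS = (0.01, 0.05, 0.1, 0.2, 0.3)
XGB_MAX_DEPTH = (2, 3, 4, 50, 100, 500)
XGB_COLSAMPLE = (0.1, 0.2, 0.3, 0.5, 0.7, 0.9)
XGB_SUBSAMPLE = (0.7, 0.8, 0.9)


class InvalidGridError(ValueError):
    pass


def _dedup(values) -> list:
    out = []
    for v in values:
        if v not in out:
            out.append(v)
    return out


def default_rf_grid(n_train: int, p: int) -> TuningGrid:
    """The forest tuning grid for a given training-fold size."""
    mtry = _dedup(max(1, p // d) for d in RF_MTRY_DIVISORS)
    nodesize = _dedup(max(1, int(f * n_train)) for f in RF_NODESIZE_FRACTIONS)
    return TuningGrid({"mtry": mtry, "nodesize": nodesize})


def default_xgb_grid() -> TuningGrid:
    return TuningGrid(
        {
            "max_depth": list(XGB_MAX_DEPTH),
            "colsample_bytree": list(XGB_COLSAMPLE),
            "subsample": list(XGB_SUBSAMPLE),
        }
    )


def _combinations(grid: TuningGrid) -> list[dict]:
    combos = [{}]
    for name, values in grid.params.items():
        combos = [{**c, name: v} for c in combos for v in values]
    return combos


def _with_features(X: np.ndarray, fixed: np.ndarray | None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if fixed is None:
        return X
    F = np.atleast_2d(np.asarray(fixed, dtype=float))
    if F.shape[0] != X.shape[0]:
        F = F.T
    return np.hstack([X, F])


def _validate_grid(grid: TuningGrid, n: int, p: int, method: str) -> None:
    for v in grid.params.get("mtry", []):
        if v > p:
            raise InvalidGridError(f"mtry={v} exceeds p={p}")
    for v in grid.params.get("nodesize", []):
        if v > n:
            raise InvalidGridError(f"nodesize={v} exceeds n={n}")


def _make_rf(params: dict, seed: int, n_trees: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=params["mtry"],
        min_samples_leaf=params["nodesize"],
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def _make_gbm(params: dict, seed: int, n_trees: int) -> GradientBoostingRegressor:
    return GradientBoostingRegressor(
        n_estimators=n_trees,
        max_depth=params["max_depth"],
        max_features=params["colsample_bytree"],
        subsample=params["subsample"],
        random_state=seed,
    )


def _tune_and_fit(
    make_estimator,
    X: np.ndarray,
    y: np.ndarray,
    grid: TuningGrid,
    seed: int,
    n_trees: int,
    method: str,
) -> FittedModel:
    y = np.asarray(y, dtype=float)
    n = len(y)
    combos = _combinations(grid)
    if len(combos) > 1:
        k = min(grid.inner_cv_folds, n)
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(kf.split(X))
        best_mse, best = np.inf, combos[0]
        for combo in combos:
            mse = 0.0
            for tr, va in splits:
                est = make_estimator(combo, seed, n_trees)
                est.fit(X[tr], y[tr])
                resid = y[va] - est.predict(X[va])
                mse += float(resid @ resid) / len(va)
            mse /= len(splits)
            if mse < best_mse:
                best_mse, best = mse, combo
    else:
        best = combos[0]
    est = make_estimator(best, seed, n_trees)
    est.fit(X, y)
    return FittedModel(
        method=method,
        intercept=float(y.mean()),
        genomic_values=est.predict(X),
        tuned_hyperparams={k: float(v) for k, v in best.items()},
        extra={"estimator": est, "n_trees": n_trees},
    )


def fit_tree_bagging(
    X: np.ndarray,
    y: np.ndarray,
    grid: TuningGrid | None = None,
    seed: int = 0,
    fixed: np.ndarray | None = None,
    n_trees: int = RF_N_TREES,
) -> FittedModel:
    """Random-Forest regression with the default mtry/nodesize grid."""
    Xf = _with_features(X, fixed)
    n, p = Xf.shape
    if n < 10:
        raise ValueError("need at least 10 training samples")
    if grid is None:
        grid = default_rf_grid(n, p)
    _validate_grid(grid, n, p, "rf")
    return _tune_and_fit(_make_rf, Xf, y, grid, seed, n_trees, "rf")


def fit_boosted_trees(
    X: np.ndarray,
    y: np.ndarray,
    grid: TuningGrid | None = None,
    seed: int = 0,
    fixed: np.ndarray | None = None,
    n_trees: int = 100,
) -> FittedModel:
    """Gradient-boosted tree regression with the default depth/subsample grid."""
    Xf = _with_features(X, fixed)
    n, p = Xf.shape
    if n < 10:
        raise ValueError("need at least 10 training samples")
    if grid is None:
        grid = default_xgb_grid()
    _validate_grid(grid, n, p, "xgboost")
    model = _tune_and_fit(_make_gbm, Xf, y, grid, seed, n_trees, "xgboost")
    return model


def predict_trees(model: FittedModel, X_test: np.ndarray, fixed: np.ndarray | None = None) -> np.ndarray:
    return model.extra["estimator"].predict(_with_features(X_test, fixed))
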