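"""GBLUP: mixed model y = mu + g + e with g ~ N(0, K sigma2_g).

Variance components are estimated by REML using a single spectral
decomposition of the kinship: with K = U diag(s) U' and variance ratio
delta = sigma2_e / sigma2_g, the covariance rotates to
diag(sigma2_g * (s + delta)), so the restricted likelihood is a cheap
1-D function of delta optimized by bounded scalar search.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .base import FitError, FittedModel
from .kinship import KinshipMatrix

__all__ = ["fit_gblup", "predict_gblup"]

_H2_BOUNDS = (1e-6, 1.0 - 1e-6)


def _design(n: int, fixed: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if fixed is not None:
        F = np.atleast_2d(np.asarray(fixed, dtype=float))
        if F.shape[0] != n:
            F = F.T
        X = np.hstack([X, F])
    return X


def _reml_neg_loglik(h2: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    n, q = Xt.shape
    delta = (1.0 - h2) / h2
    w = s + delta  # V / sigma2_g in the eigenbasis
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    try:
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - Xt @ beta
    quad = np.sum(r * r / w)
    if quad <= 0:
        return np.inf
    sigma2_g = quad / (n - q)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    ll = -0.5 * ((n - q) * (np.log(sigma2_g) + 1.0) + np.sum(np.log(w)) + logdet_xwx)
    return -ll


def fit_gblup(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    fixed: np.ndarray | None = None,
) -> FittedModel:
    """REML fit of the single-kinship mixed model.

    Parameters
    ----------
    y : training phenotypes (n,)
    K : kinship among the training samples
    fixed : optional covariates entering as fixed effects (with intercept)
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("phenotypes must be finite")
    Kmat = K.matrix if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    n = len(y)
    if Kmat.shape != (n, n):
        raise ValueError("kinship dimension does not match y")
    X = _design(n, fixed)

    s, U = np.linalg.eigh(Kmat)
    if s.min() < -1e-4:
        raise FitError(f"kinship has eigenvalue {s.min():.3g}; not PSD")
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    res = minimize_scalar(
        _reml_neg_loglik,
        bounds=_H2_BOUNDS,
        args=(s, yt, Xt),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise FitError("REML optimization failed to find a finite likelihood")
    h2 = float(res.x)
    delta = (1.0 - h2) / h2
    w = s + delta
    Xw = Xt / w[:, None]
    beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    r = yt - Xt @ beta
    sigma2_g = float(np.sum(r * r / w) / (n - X.shape[1]))
    sigma2_e = float(delta * sigma2_g)

    # BLUP of g on the training samples: K (K + delta I)^-1 (y - X beta)
    alpha = U @ (r / w)  # (K + delta I)^-1 residual
    g_hat = U @ (s * (r / w))
    return FittedModel(
        method="gblup",
        intercept=float(beta[0]),
        genomic_values=g_hat,
        variance_components={"sigma2_g": sigma2_g, "sigma2_e": sigma2_e},
        fixed_effects=beta,
        extra={
            "alpha": alpha,
            "h2_reml": h2,
            "delta": delta,
            "design_columns": X.shape[1],
            "reml_loglik": -float(res.fun),
        },
    )


def predict_gblup(
    model: FittedModel,
    K_cross: np.ndarray,
    fixed: np.ndarray | None = None,
) -> np.ndarray:
    """Predict test genomic values from the test-x-train kinship block.

    Returns X_test beta + K_cross alpha where alpha was precomputed from
    the training fit. ``fixed`` must be supplied iff the model was fitted
    with covariates.
    """
    K_cross = np.asarray(K_cross, dtype=float)
    X_test = _design(K_cross.shape[0], fixed)
    if X_test.shape[1] != model.extra["design_columns"]:
        raise ValueError("test covariates do not match the training design")
    return X_test @ model.fixed_effects + K_cross @ model.extra["alpha"]
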