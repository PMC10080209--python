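"""Multi-kernel RKHS regression via a Bayesian Gibbs sampler.

Model: y = mu + W b + sum_l g_l + e with g_l ~ N(0, K_l sigma2_gl).
Each kernel is eigendecomposed once; the genetic components are sampled
in their eigenbases, where the conditional posteriors are diagonal.
Default usage passes Gaussian kernels at bandwidths {0.2, 0.5, 0.8}
(kernel averaging as three separately weighted random components); a
single averaged kernel can be fitted by passing that kernel alone.

GBLUP is the special case of a single linear (VanRaden) kernel.
"""

from __future__ import annotations

import numpy as np

from .base import FitError, FittedModel, MCMCSettings
from .kinship import KinshipMatrix

__all__ = ["fit_rkhs", "predict_rkhs", "average_kernels"]

_EIG_TOL = 1e-10

#: default Gaussian bandwidths for kernel averaging
DEFAULT_BANDWIDTHS = (0.2, 0.5, 0.8)


def average_kernels(kernels: list[KinshipMatrix]) -> KinshipMatrix:
    """Plain average of the kernel matrices (single-kernel mode)."""
    mats = [K.matrix for K in kernels]
    return KinshipMatrix(
        sum(mats) / len(mats),
        kind="gaussian",
        source_marker_count=kernels[0].source_marker_count,
        bandwidth=None,
    )


def fit_rkhs(
    y: np.ndarray,
    kernels: list[KinshipMatrix] | list[np.ndarray],
    settings: MCMCSettings | None = None,
    fixed: np.ndarray | None = None,
) -> FittedModel:
    """Fit the multi-component kernel regression by Gibbs sampling.

    Returns per-kernel variance components ``sigma2_g1..sigma2_gL`` and
    the summed posterior-mean genomic values.
    """
    settings = settings or MCMCSettings()
    y = np.asarray(y, dtype=float)
    n = len(y)
    mats = [K.matrix if isinstance(K, KinshipMatrix) else np.asarray(K, float) for K in kernels]
    if not mats:
        raise ValueError("need at least one kernel")
    for K in mats:
        if K.shape != (n, n):
            raise ValueError("kernel dimension does not match y")
    if fixed is not None:
        W = np.atleast_2d(np.asarray(fixed, dtype=float))
        if W.shape[0] != n:
            W = W.T
    else:
        W = np.zeros((n, 0))
    k_fixed = W.shape[1]
    wtw = (W**2).sum(axis=0)

    L = len(mats)
    eig = []
    for K in mats:
        s, U = np.linalg.eigh(K)
        keep = s > max(_EIG_TOL, s.max() * 1e-12)
        eig.append((s[keep], U[:, keep]))

    rng = np.random.default_rng(settings.seed)
    nu = settings.prior_df
    vy = max(float(np.var(y)), 1e-8)
    S_e = (1.0 - settings.prior_R2) * vy * (nu + 2.0) / nu
    S_l = []
    for s, _ in eig:
        mean_diag = s.sum() / n  # ~ trace(K)/n
        S_l.append(settings.prior_R2 * vy * (nu + 2.0) / nu / (L * max(mean_diag, 1e-12)))

    mu = float(y.mean())
    bw = np.zeros(k_fixed)
    gamma = [np.zeros(len(s)) for s, _ in eig]
    g = [np.zeros(n) for _ in range(L)]
    sigma2_l = [settings.prior_R2 * vy / L] * L
    sigma2_e = vy * (1.0 - settings.prior_R2)
    e = y - mu

    n_saved = 0
    sum_mu = 0.0
    sum_bw = np.zeros(k_fixed)
    sum_g = [np.zeros(n) for _ in range(L)]
    sum_alpha = [np.zeros(n) for _ in range(L)]
    sum_s2l = np.zeros(L)
    sum_s2e = 0.0

    for it in range(settings.n_iter):
        e += mu
        mu = e.sum() / n + np.sqrt(sigma2_e / n) * rng.standard_normal()
        e -= mu
        for c in range(k_fixed):
            if wtw[c] <= 0:
                continue
            e += W[:, c] * bw[c]
            rhs = W[:, c] @ e
            bw[c] = rhs / wtw[c] + np.sqrt(sigma2_e / wtw[c]) * rng.standard_normal()
            e -= W[:, c] * bw[c]
        for l in range(L):
            s, U = eig[l]
            r = e + g[l]
            rt = U.T @ r
            prec = 1.0 / (s * sigma2_l[l]) + 1.0 / sigma2_e
            v = 1.0 / prec
            m = v * rt / sigma2_e
            gamma[l] = m + np.sqrt(v) * rng.standard_normal(len(s))
            g[l] = U @ gamma[l]
            e = r - g[l]
            quad = float(np.sum(gamma[l] ** 2 / s))
            sigma2_l[l] = (quad + nu * S_l[l]) / rng.chisquare(len(s) + nu)
        sigma2_e = (e @ e + nu * S_e) / rng.chisquare(n + nu)
        if not np.isfinite(sigma2_e) or sigma2_e <= 0:
            raise FitError(f"rkhs sampler diverged at iteration {it + 1}")
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            n_saved += 1
            sum_mu += mu
            sum_bw += bw
            sum_s2e += sigma2_e
            for l in range(L):
                s, U = eig[l]
                sum_g[l] += g[l]
                sum_alpha[l] += U @ (gamma[l] / s)  # K_l^+ g_l, for prediction
                sum_s2l[l] += sigma2_l[l]

    if n_saved == 0:
        raise FitError("no posterior samples collected")
    g_mean = [sg / n_saved for sg in sum_g]
    vc = {f"sigma2_g{l + 1}": float(sum_s2l[l] / n_saved) for l in range(L)}
    vc["sigma2_e"] = float(sum_s2e / n_saved)
    return FittedModel(
        method="rkhs",
        intercept=float(sum_mu / n_saved),
        genomic_values=sum(g_mean),
        variance_components=vc,
        fixed_effects=(sum_bw / n_saved) if k_fixed else None,
        extra={
            "alphas": [sa / n_saved for sa in sum_alpha],
            "n_kernels": L,
            "n_saved": n_saved,
        },
    )


def predict_rkhs(
    model: FittedModel,
    K_cross: list[np.ndarray],
    fixed: np.ndarray | None = None,
) -> np.ndarray:
    """mu + sum_l K_cross_l alpha_l (+ W b) for test samples."""
    alphas = model.extra["alphas"]
    if len(K_cross) != len(alphas):
        raise ValueError("one cross-kernel block per fitted kernel required")
    pred = model.intercept + sum(
        np.asarray(Kc, float) @ a for Kc, a in zip(K_cross, alphas)
    )
    if model.fixed_effects is not None:
        if fixed is None:
            raise ValueError("model was fitted with covariates; supply them")
        W = np.atleast_2d(np.asarray(fixed, dtype=float))
        if W.shape[0] != pred.shape[0]:
            W = W.T
        pred = pred + W @ model.fixed_effects
    return pred
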