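"""Additive/epistatic variance decomposition with two kinships.

Model: y = mu + g_a + g_e + e with g_a ~ N(0, sigma2_a G),
g_e ~ N(0, sigma2_e E) and E the elementwise square of the GRM. The
ratio sigma2_a / sigma2_e is the trait-complexity proxy; the additive
fraction sigma2_a / (sigma2_a + sigma2_e + sigma2_res) is what empirical
heritability estimates report.

The default engine is average-information REML with boundary clamping at
zero and step halving on likelihood decreases; an MCMC engine (the
multi-kernel Gibbs sampler) serves as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpmodels import KinshipMatrix, MCMCSettings, fit_rkhs
from .gpmodels.base import FitError

__all__ = ["VarianceComponents", "fit_additive_epistatic_lmm", "additivity_ratio"]

_BOUNDARY_FLOOR_FRAC = 1e-6


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    sigma2_res: float
    converged: bool = True
    n_iter: int = 0
    at_boundary: tuple[str, ...] = ()
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_e", "sigma2_res"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def additivity_ratio(self) -> float:
        return additivity_ratio(self)

    @property
    def additive_fraction(self) -> float:
        total = self.sigma2_a + self.sigma2_e + self.sigma2_res
        return self.sigma2_a / total if total > 0 else 0.0

    @property
    def total_variance(self) -> float:
        return self.sigma2_a + self.sigma2_e + self.sigma2_res


def additivity_ratio(vc: VarianceComponents) -> float:
    """sigma2_a / sigma2_e; +inf when the epistatic component is at zero."""
    if vc.sigma2_e <= 0 or "sigma2_e" in vc.at_boundary:
        return float("inf")
    return vc.sigma2_a / vc.sigma2_e


def _reml_loglik(theta: np.ndarray, Vs: list[np.ndarray], y: np.ndarray, X: np.ndarray):
    """Restricted log-likelihood and the projection pieces it needs."""
    n, q = X.shape
    V = sum(t * Vi for t, Vi in zip(theta, Vs))
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return None
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    C = XtVinv @ X
    Cinv = np.linalg.inv(C)
    P = Vinv - XtVinv.T @ Cinv @ XtVinv
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    sign, logdet_C = np.linalg.slogdet(C)
    if sign <= 0:
        return None
    Py = P @ y
    ll = -0.5 * (logdet_V + logdet_C + y @ Py)
    return ll, P, Py


def fit_additive_epistatic_lmm(
    y: np.ndarray,
    G: KinshipMatrix | np.ndarray,
    E: KinshipMatrix | np.ndarray,
    engine: str = "reml",
    max_iter: int = 100,
    tol: float = 1e-6,
    mcmc_settings: MCMCSettings | None = None,
) -> VarianceComponents:
    """Estimate (sigma2_a, sigma2_e, sigma2_res) for the two-kinship model."""
    y = np.asarray(y, dtype=float)
    Gm = G.matrix if isinstance(G, KinshipMatrix) else np.asarray(G, float)
    Em = E.matrix if isinstance(E, KinshipMatrix) else np.asarray(E, float)
    n = len(y)
    if Gm.shape != (n, n) or Em.shape != (n, n):
        raise ValueError("kinship dimensions do not match y")
    if engine == "mcmc":
        settings = mcmc_settings or MCMCSettings(n_iter=3000, burn_in=500, thin=2, seed=0)
        model = fit_rkhs(y, [Gm, Em], settings=settings)
        vc = model.variance_components
        return VarianceComponents(
            sigma2_a=vc["sigma2_g1"],
            sigma2_e=vc["sigma2_g2"],
            sigma2_res=vc["sigma2_e"],
            converged=True,
            n_iter=settings.n_iter,
        )
    if engine != "reml":
        raise ValueError("engine must be 'reml' or 'mcmc'")

    X = np.ones((n, 1))
    Vs = [Gm, Em, np.eye(n)]
    vy = float(np.var(y, ddof=1))
    floor = _BOUNDARY_FLOOR_FRAC * vy
    theta = np.array([vy / 3.0, vy / 3.0, vy / 3.0])
    evaluated = _reml_loglik(theta, Vs, y, X)
    if evaluated is None:
        raise FitError("initial REML likelihood undefined")
    ll, P, Py = evaluated
    trajectory = [float(ll)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        VPy = [Vi @ Py for Vi in Vs]
        grad = np.array(
            [-0.5 * (np.trace(P @ Vi) - Py @ VPy_i) for Vi, VPy_i in zip(Vs, VPy)]
        )
        PVPy = [P @ v for v in VPy]
        AI = 0.5 * np.array([[VPy[i] @ PVPy[j] for j in range(3)] for i in range(3)])
        try:
            step = np.linalg.solve(AI + 1e-10 * np.eye(3), grad)
        except np.linalg.LinAlgError:
            step = grad / max(np.abs(grad).max(), 1.0)
        # step halving with boundary clamping
        improved = False
        for _ in range(12):
            cand = np.maximum(theta + step, floor)
            evaluated = _reml_loglik(cand, Vs, y, X)
            if evaluated is not None and evaluated[0] >= ll - 1e-10:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        new_ll, P, Py = evaluated
        delta = np.abs(cand - theta).max()
        theta = cand
        trajectory.append(float(new_ll))
        if abs(new_ll - ll) < tol and delta < tol * max(vy, 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged and it >= max_iter:
        raise FitError(f"AI-REML did not converge in {max_iter} iterations; trajectory={trajectory}")
    boundary = tuple(
        name
        for name, val in zip(("sigma2_a", "sigma2_e", "sigma2_res"), theta)
        if val <= floor * 1.01
    )
    theta = np.where(theta <= floor * 1.01, 0.0, theta)
    return VarianceComponents(
        sigma2_a=float(theta[0]),
        sigma2_e=float(theta[1]),
        sigma2_res=float(theta[2]),
        converged=True,
        n_iter=it,
        at_boundary=boundary,
        loglik=float(ll),
    )
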