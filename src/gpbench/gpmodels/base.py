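"""Shared fitted-model container and settings types."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FittedModel", "MCMCSettings", "TuningGrid", "FitError"]

METHODS = ("gblup", "bayesA", "bayesB", "rkhs", "rf", "xgboost")


class FitError(RuntimeError):
    pass


@dataclass
class MCMCSettings:
    """Gibbs-sampler controls for the Bayesian regressions.

    prior_R2 is the fraction of phenotypic variance a priori attributed
    to markers; it fixes the scale of the scaled-inverse-chi-square
    variance priors (degrees of freedom ``prior_df``).
    """

    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    seed: int | None = None
    prior_df: float = 5.0
    prior_R2: float = 0.5

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.prior_R2 < 1:
            raise ValueError("prior_R2 must lie in (0, 1)")


@dataclass
class TuningGrid:
    """Hyperparameter candidates searched by inner k-fold CV."""

    params: dict[str, list]
    inner_cv_folds: int = 5

    def __post_init__(self) -> None:
        for name, values in self.params.items():
            if len(values) == 0:
                raise ValueError(f"empty candidate list for {name!r}")


@dataclass
class FittedModel:
    """Result of fitting one genomic-prediction method.

    Only the fields relevant to the method are populated: marker_effects
    for the Bayesian regressions, variance_components for the mixed
    models, tuned_hyperparams for the tree ensembles.
    """

    method: str
    intercept: float
    genomic_values: np.ndarray
    marker_effects: np.ndarray | None = None
    variance_components: dict[str, float] = field(default_factory=dict)
    tuned_hyperparams: dict[str, float] = field(default_factory=dict)
    fixed_effects: np.ndarray | None = None
    extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        for name, value in self.variance_components.items():
            if value < -1e-12:
                raise ValueError(f"negative variance component {name}={value}")

    def summary(self) -> dict:
        """JSON-serializable fit summary."""
        out = {
            "method": self.method,
            "intercept": float(self.intercept),
            "variance_components": {k: float(v) for k, v in self.variance_components.items()},
            "tuned_hyperparams": {k: float(v) for k, v in self.tuned_hyperparams.items()},
        }
        if self.marker_effects is not None:
            out["n_markers"] = int(len(self.marker_effects))
        return out
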