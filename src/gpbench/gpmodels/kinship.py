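"""Kinship constructions: VanRaden GRM, Gaussian kernel, Hadamard square."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..genosim import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "KinshipError",
    "grm_vanraden",
    "gaussian_kernel",
    "hadamard_kinship",
]

PSD_JITTER = 1e-8
PSD_ABORT = 1e-4


class KinshipError(ValueError):
    pass


@dataclass
class KinshipMatrix:
    """Symmetric n x n similarity matrix with provenance."""

    matrix: np.ndarray
    kind: str  # "vanraden" | "gaussian" | "hadamard"
    source_marker_count: int
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise KinshipError("kinship must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise KinshipError("kinship must be symmetric")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.matrix[np.ix_(rows, cols)]

    def submatrix(self, idx: np.ndarray) -> "KinshipMatrix":
        return KinshipMatrix(
            self.matrix[np.ix_(idx, idx)],
            kind=self.kind,
            source_marker_count=self.source_marker_count,
            bandwidth=self.bandwidth,
        )


def _dosage_array(G) -> np.ndarray:
    if isinstance(G, GenotypeMatrix):
        return G.dosages.astype(np.float64)
    return np.asarray(G, dtype=np.float64)


def grm_vanraden(G: GenotypeMatrix | np.ndarray) -> KinshipMatrix:
    """Genomic relationship matrix from centered dosages.

    W holds dosages centered by twice the allele frequency per locus;
    GRM = W W' / (2 * sum_k f_k (1 - f_k)).
    """
    X = _dosage_array(G)
    n, p = X.shape
    f = X.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(f * (1.0 - f))
    if denom <= 0 or not (X.var(axis=0) > 0).any():
        raise KinshipError("all markers monomorphic; GRM undefined")
    W = X - 2.0 * f
    K = (W @ W.T) / denom
    return KinshipMatrix(K, kind="vanraden", source_marker_count=p)


def gaussian_kernel(G: GenotypeMatrix | np.ndarray, b: float) -> KinshipMatrix:
    """K_ij = exp(-b * mean squared dosage difference), unit diagonal."""
    if b < 0:
        raise ValueError("bandwidth must be >= 0")
    X = _dosage_array(G)
    n, p = X.shape
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-b * d2 / p)
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(K, kind="gaussian", source_marker_count=p, bandwidth=b)


def hadamard_kinship(K: KinshipMatrix) -> KinshipMatrix:
    """Elementwise square K o K (epistatic relationship matrix)."""
    return KinshipMatrix(
        K.matrix * K.matrix,
        kind="hadamard",
        source_marker_count=K.source_marker_count,
    )


def ensure_psd(K: np.ndarray, jitter: float = PSD_JITTER, abort: float = PSD_ABORT) -> np.ndarray:
    """Return K with minimal diagonal jitter so it passes Cholesky.

    Jitter escalates by factors of 10 from ``jitter``; beyond ``abort``
    the matrix is considered broken.
    """
    eps = 0.0
    while True:
        try:
            np.linalg.cholesky(K + eps * np.eye(K.shape[0]))
            return K + eps * np.eye(K.shape[0]) if eps else K
        except np.linalg.LinAlgError:
            eps = jitter if eps == 0.0 else eps * 10.0
            if eps > abort:
                raise KinshipError(f"kinship not PSD within jitter {abort}")
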