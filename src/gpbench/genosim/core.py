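"""Genotype simulation and marker statistics.

Dosage matrices are n samples x p markers with values in {0, 1, 2}
(0 = AA, 1 = Aa, 2 = aa). Loci are simulated independently: each dosage
is a Binomial(2, maf) draw, so no linkage is present unless constructed
explicitly (see :mod:`gpbench.structld`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "LDTable",
    "simulate_genotypes",
    "compute_maf",
    "maf_filter",
    "pairwise_r2",
    "ld_prune",
]

#: number of synthetic chromosomes markers are assigned to (round-robin)
N_SYNTHETIC_CHROMOSOMES = 5
#: physical spacing between consecutive markers on a synthetic chromosome
SYNTHETIC_SPACING_BP = 1000


class UndefinedLDError(ValueError):
    """Raised when r2 is requested for a zero-variance marker."""


@dataclass
class GenotypeMatrix:
    """Integer dosage matrix with a marker map.

    Attributes
    ----------
    dosages : ndarray of shape (n, p), values in {0, 1, 2}
    sample_ids : ndarray of n strings
    marker_ids : ndarray of p strings
    chromosome : ndarray of p labels
    position_bp : ndarray of p positive ints (1-based physical positions)
    seed : seed used to generate the matrix, if simulated
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    marker_ids: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must take values in {0, 1, 2}")
        self.dosages = self.dosages.astype(np.int8, copy=False)
        n, p = self.dosages.shape
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if len(self.sample_ids) != n:
            raise ValueError(f"sample_ids has length {len(self.sample_ids)}, expected {n}")
        for name in ("marker_ids", "chromosome", "position_bp"):
            if len(getattr(self, name)) != p:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, expected {p}")
        if (self.position_bp < 0).any():
            raise ValueError("positions must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given marker indices (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            sample_ids=self.sample_ids,
            marker_ids=self.marker_ids[index],
            chromosome=self.chromosome[index],
            position_bp=self.position_bp[index],
            seed=self.seed,
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index],
            sample_ids=self.sample_ids[index],
            marker_ids=self.marker_ids,
            chromosome=self.chromosome,
            position_bp=self.position_bp,
            seed=self.seed,
        )


@dataclass
class LDTable:
    """Pairwise squared-correlation records (marker_i, marker_j, r2)."""

    pairs: list[tuple[int, int, float]]


def _default_marker_map(p: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Round-robin assignment of p markers to synthetic chromosomes.

    Marker k goes to chromosome (k mod 5) + 1 at position
    (k // 5 + 1) * 1000 bp, so positions are evenly spaced and strictly
    increasing within each chromosome.
    """
    idx = np.arange(p)
    chrom = np.array([f"chr{(k % N_SYNTHETIC_CHROMOSOMES) + 1}" for k in idx], dtype=object)
    pos = (idx // N_SYNTHETIC_CHROMOSOMES + 1) * SYNTHETIC_SPACING_BP
    ids = np.array([f"snp{k}" for k in idx], dtype=object)
    return ids, chrom, pos.astype(np.int64)


def simulate_genotypes(
    n: int,
    p: int,
    maf: float | np.ndarray = 0.4,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Simulate a diploid dosage matrix with i.i.d. binomial loci.

    Each dosage is a Binomial(2, maf) draw, independently per locus and
    per sample. ``maf`` may be a scalar (fixed frequency at every locus,
    the default experimental setting) or a length-p vector of per-locus
    frequencies.

    Parameters
    ----------
    n, p : sample and marker counts (n >= 2, p >= 1)
    maf : allele frequency in (0, 0.5], scalar or per-locus
    seed : RNG seed; recorded on the output
    """
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    if p < 1:
        raise ValueError(f"need at least 1 marker, got {p}")
    maf_arr = np.broadcast_to(np.asarray(maf, dtype=float), (p,))
    if (maf_arr <= 0).any() or (maf_arr > 0.5).any():
        raise ValueError("maf must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, maf_arr, size=(n, p)).astype(np.int8)
    ids, chrom, pos = _default_marker_map(p)
    samples = np.array([f"sample{i}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosages, samples, ids, chrom, pos, seed=seed)


def compute_maf(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-marker minor allele frequency: min(f, 1 - f), f = mean dosage / 2."""
    X = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G)
    f = X.mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def maf_filter(G: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Retain markers with MAF strictly greater than ``threshold``."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    keep = np.flatnonzero(compute_maf(G) > threshold)
    if keep.size == 0:
        warnings.warn("MAF filter removed every marker", stacklevel=2)
    return G.subset_markers(keep)


def pairwise_r2(G: GenotypeMatrix | np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation between dosage columns i and j."""
    X = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G)
    xi = X[:, i].astype(float)
    xj = X[:, j].astype(float)
    xi -= xi.mean()
    xj -= xj.mean()
    vi = xi @ xi
    vj = xj @ xj
    if vi == 0.0 or vj == 0.0:
        raise UndefinedLDError(f"zero-variance marker in pair ({i}, {j})")
    c = xi @ xj
    return float(min(c * c / (vi * vj), 1.0))


def _r2_matrix(X: np.ndarray) -> np.ndarray:
    """Dense r2 matrix of dosage columns; zero-variance columns give nan."""
    Xc = X.astype(float) - X.mean(axis=0, keepdims=True)
    sd = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc.T @ Xc) / np.outer(sd, sd)
    return np.clip(R**2, 0.0, 1.0)


def ld_prune(
    G: GenotypeMatrix,
    window: int = 500,
    stride: int = 50,
    r2_threshold: float = 0.1,
) -> GenotypeMatrix:
    """Sliding-window greedy LD pruning (PLINK ``--indep-pairwise`` style).

    Within each window of ``window`` retained markers, while any retained
    pair has r2 > ``r2_threshold`` the later-indexed member of the worst
    offending pair is removed; the window then advances by ``stride``
    markers. Marker order is preserved in the output. Monomorphic markers
    never trigger removal (their r2 is undefined).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 0 < stride <= window:
        raise ValueError("stride must satisfy 0 < stride <= window")
    p = G.n_markers
    keep = np.ones(p, dtype=bool)
    X = G.dosages
    start = 0
    while start < p:
        stop = min(start + window, p)
        idx = np.flatnonzero(keep[start:stop]) + start
        if idx.size > 1:
            R2 = _r2_matrix(X[:, idx])
            np.fill_diagonal(R2, 0.0)
            R2 = np.nan_to_num(R2, nan=0.0)
            active = np.ones(idx.size, dtype=bool)
            while True:
                sub = np.where(active)[0]
                if sub.size < 2:
                    break
                block = R2[np.ix_(sub, sub)]
                flat = np.argmax(block)
                a, b = divmod(flat, sub.size)
                if block[a, b] <= r2_threshold:
                    break
                # remove the later-indexed member of the worst pair
                active[sub[max(a, b)]] = False
            keep[idx[~active]] = False
        if stop == p:
            break
        start += stride
    return G.subset_markers(np.flatnonzero(keep))
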