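"""Population-structure and SNP-QTN linkage-disequilibrium experiments.

Structure experiment: each method is run twice on identical CV folds,
without and with the top-k principal components of the scaled dosage
matrix (fixed effects for kinship/Bayesian methods, extra features for
tree ensembles); delta_mu is the mean paired accuracy difference.

LD experiment: one model per method is trained on the causal markers
plus cross-chromosome fillers, another on QTN-linked SNPs (nearest on
the genome, drawn from a low- or high-LD pool) plus the same fillers;
delta_r is the difference of median accuracies. Synthetic LD partners
are manufactured by copying a causal column and resampling a controlled
fraction of entries until the pairwise r2 lands in the target band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evalharness import benchmark_scenario
from .genosim import GenotypeMatrix, pairwise_r2
from .phenosim import TraitArchitecture, genetic_value_additive

__all__ = [
    "PCSet",
    "LDExperimentDesign",
    "pca_dosages",
    "ps_experiment",
    "partition_by_ld",
    "nearest_linked_snp",
    "build_ld_experiment",
    "delta_r",
    "simulate_structured_genotypes",
    "simulate_ld_genotypes",
    "simulate_preset_trait",
    "ld_experiment",
]

LOW_LD_THRESHOLD = 0.5
HIGH_LD_THRESHOLD = 0.9


class DesignError(ValueError):
    pass


@dataclass
class PCSet:
    """Top principal components of the scaled dosage matrix."""

    scores: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,), descending
    k: int


@dataclass
class LDExperimentDesign:
    qtn_set: np.ndarray
    linked_set: np.ndarray
    filler_set: np.ndarray
    ld_regime: str  # "low" | "high"
    total_markers: int
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.qtn_set = np.asarray(self.qtn_set, dtype=np.int64)
        self.linked_set = np.asarray(self.linked_set, dtype=np.int64)
        self.filler_set = np.asarray(self.filler_set, dtype=np.int64)
        if self.ld_regime not in ("low", "high"):
            raise ValueError("ld_regime must be 'low' or 'high'")
        if len(self.qtn_set) != len(self.linked_set):
            raise ValueError("one linked SNP per QTN required")
        if np.intersect1d(self.qtn_set, self.linked_set).size:
            raise ValueError("linked set must be disjoint from the QTN set")


def pca_dosages(G: GenotypeMatrix | np.ndarray, k: int = 10) -> PCSet:
    """PCA of the column-centered, unit-variance dosage matrix.

    Zero-variance columns must be filtered beforehand. Eigenvalues are
    singular values squared over (n - 1).
    """
    X = G.dosages.astype(float) if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    n, p = X.shape
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n, p)={min(n, p)}")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance columns present; apply a MAF filter first")
    Z = (X - X.mean(axis=0)) / sd
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    eigenvalues = S[:k] ** 2 / (n - 1)
    return PCSet(scores=scores, eigenvalues=eigenvalues, k=k)


def ps_experiment(
    G: GenotypeMatrix,
    phenotypes: np.ndarray,
    methods,
    k: int = 10,
    cv_folds: int = 5,
    cv_repeats: int = 5,
    seed: int = 0,
    options: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired corrected/uncorrected benchmark on identical folds.

    Returns (uncorrected table, corrected table, delta_mu per method)
    where delta_mu is the mean over paired (trait, repeat, fold) cells of
    r_corrected - r_uncorrected.
    """
    pcs = pca_dosages_safe(G, k)
    base_opts = dict(options or {})
    acc_plain = benchmark_scenario(
        G, phenotypes, methods, scenario_id="uncorrected",
        k=cv_folds, repeats=cv_repeats, seed=seed, options={**base_opts, "fixed": None},
    )
    acc_corr = benchmark_scenario(
        G, phenotypes, methods, scenario_id="corrected",
        k=cv_folds, repeats=cv_repeats, seed=seed, options={**base_opts, "fixed": pcs.scores},
    )
    delta_mu = {}
    keys = ["trait", "repeat", "fold"]
    for method in methods:
        a = acc_plain[acc_plain["method"] == method].set_index(keys)["r"]
        b = acc_corr[acc_corr["method"] == method].set_index(keys)["r"]
        diff = (b - a).dropna()
        delta_mu[method] = float(diff.mean())
    return acc_plain, acc_corr, delta_mu


def pca_dosages_safe(G: GenotypeMatrix, k: int) -> PCSet:
    """PCA after silently dropping monomorphic columns."""
    X = G.dosages.astype(float)
    keep = X.std(axis=0) > 0
    return pca_dosages(X[:, keep], k=k)


def partition_by_ld(
    G: GenotypeMatrix,
    qtn_set: np.ndarray,
    low_threshold: float = LOW_LD_THRESHOLD,
    high_threshold: float = HIGH_LD_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Split non-QTN markers into low/high-LD pools.

    Membership uses each marker's maximum r2 against the QTN set: the low
    pool takes r2 <= low_threshold (inclusive), the high pool
    r2 > high_threshold; intermediate markers belong to neither.
    Monomorphic markers count as unlinked (r2 = 0).
    """
    qtn_set = np.asarray(qtn_set, dtype=np.int64)
    if qtn_set.size == 0:
        raise ValueError("qtn_set must be non-empty")
    X = G.dosages.astype(float)
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    Q = Xc[:, qtn_set]
    qn = norms[qtn_set]
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc.T @ Q) / np.outer(norms, qn)
    R2 = np.clip(R**2, 0.0, 1.0)
    r2max = np.nan_to_num(np.max(R2, axis=1), nan=0.0)
    others = np.setdiff1d(np.arange(G.n_markers), qtn_set)
    low = others[r2max[others] <= low_threshold]
    high = others[r2max[others] > high_threshold]
    if low.size == 0 or high.size == 0:
        warnings.warn("an LD pool is empty", stacklevel=2)
    return low, high


def nearest_linked_snp(qtn_index: int, pool: np.ndarray, G: GenotypeMatrix) -> int:
    """Pool member on the QTN's chromosome closest in physical position.

    Ties break toward the lower position.
    """
    pool = np.asarray(pool, dtype=np.int64)
    chrom = G.chromosome[qtn_index]
    same = pool[G.chromosome[pool] == chrom]
    if same.size == 0:
        raise DesignError(f"no same-chromosome candidate for QTN {qtn_index}")
    dist = np.abs(G.position_bp[same] - G.position_bp[qtn_index])
    best = dist.min()
    candidates = same[dist == best]
    return int(candidates[np.argmin(G.position_bp[candidates])])


def build_ld_experiment(
    G: GenotypeMatrix,
    q: int = 5,
    regime: str = "low",
    qtn_chrom: str = "chr1",
    filler_chrom: str = "chr2",
    total: int = 500,
    seed: int | None = None,
    qtn_set: np.ndarray | None = None,
) -> tuple[LDExperimentDesign, np.ndarray, np.ndarray]:
    """Assemble the two marker sets of the LD experiment.

    QTNs (given or sampled) and their linked SNPs are restricted to
    ``qtn_chrom``; the shared fillers come from ``filler_chrom``. Returns
    (design, qtn-model markers, snp-model markers), both of size
    ``total`` and differing in exactly q columns.
    """
    if qtn_chrom == filler_chrom:
        raise DesignError("QTN and filler chromosomes must differ")
    rng = np.random.default_rng(seed)
    chr1 = np.flatnonzero(G.chromosome == qtn_chrom)
    if qtn_set is None:
        if q > chr1.size:
            raise DesignError(f"chromosome {qtn_chrom} has only {chr1.size} markers")
        qtn_set = np.sort(rng.choice(chr1, size=q, replace=False))
    else:
        qtn_set = np.asarray(qtn_set, dtype=np.int64)
        q = len(qtn_set)
    low, high = partition_by_ld(G, qtn_set)
    pool = low if regime == "low" else high
    pool = pool[G.chromosome[pool] == qtn_chrom]
    linked = []
    remaining = pool.copy()
    for qi in qtn_set:
        if remaining.size == 0:
            raise DesignError(f"{regime}-LD pool exhausted on {qtn_chrom}")
        snp = nearest_linked_snp(int(qi), remaining, G)
        linked.append(snp)
        remaining = remaining[remaining != snp]
    linked = np.asarray(linked, dtype=np.int64)
    fillers_avail = np.flatnonzero(G.chromosome == filler_chrom)
    n_fill = total - q
    if n_fill < 0:
        raise DesignError("total must be >= q")
    if fillers_avail.size < n_fill:
        raise DesignError(
            f"need {n_fill} fillers on {filler_chrom}, only {fillers_avail.size} available"
        )
    fillers = np.sort(rng.choice(fillers_avail, size=n_fill, replace=False))
    design = LDExperimentDesign(
        qtn_set=qtn_set,
        linked_set=linked,
        filler_set=fillers,
        ld_regime=regime,
        total_markers=total,
        seed=seed,
    )
    qtn_model = np.sort(np.concatenate([qtn_set, fillers]))
    snp_model = np.sort(np.concatenate([linked, fillers]))
    return design, qtn_model, snp_model


def delta_r(acc_qtn_model, acc_snp_model) -> float:
    """median(QTN-model accuracies) - median(SNP-model accuracies)."""
    a = np.asarray(acc_qtn_model, dtype=float)
    b = np.asarray(acc_snp_model, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("accuracy lists must be non-empty")
    return float(np.median(a) - np.median(b))


# ---------------------------------------------------------------------------
# synthetic data for both experiments


def simulate_structured_genotypes(
    n: int,
    p: int,
    n_subpop: int = 2,
    divergence: float = 0.2,
    base_freq: float = 0.4,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Two-or-more-cluster population with subpopulation frequency shifts.

    Each locus gets per-subpopulation allele frequencies drawn around
    ``base_freq`` with SD ``divergence`` (clipped away from fixation).
    Returns the genotype matrix and the subpopulation label per sample.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_subpop), np.diff(np.linspace(0, n, n_subpop + 1).astype(int)))
    freqs = np.clip(
        base_freq + rng.normal(0.0, divergence, size=(n_subpop, p)), 0.05, 0.95
    )
    dosages = rng.binomial(2, freqs[labels, :]).astype(np.int8)
    from .genosim.core import _default_marker_map

    ids, chrom, pos = _default_marker_map(p)
    samples = np.array([f"sample{i}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosages, samples, ids, chrom, pos, seed=seed), labels


def _make_ld_partner(
    x: np.ndarray,
    r2_band: tuple[float, float],
    maf: float,
    rng: np.random.Generator,
    max_tries: int = 300,
) -> np.ndarray:
    """Copy x and resample entries until pairwise r2 lands in the band."""
    lo, hi = r2_band
    n = len(x)
    frac = 1.0 - np.sqrt((lo + hi) / 2.0)  # resampled fraction; r ~ kept fraction
    for _ in range(max_tries):
        partner = x.copy()
        k = max(1, int(round(frac * n))) if frac > 0 else 0
        if k:
            idx = rng.choice(n, size=k, replace=False)
            partner[idx] = rng.binomial(2, maf, size=k).astype(x.dtype)
        if partner.std() == 0:
            continue
        r2 = np.corrcoef(x.astype(float), partner.astype(float))[0, 1] ** 2
        if lo < r2 <= hi:
            return partner
        frac *= 1.15 if r2 > hi else 0.85
        frac = min(max(frac, 0.0), 0.95)
    raise DesignError(f"could not manufacture a partner in r2 band ({lo}, {hi}]")


def simulate_ld_genotypes(
    n: int,
    q: int = 5,
    regime: str = "low",
    n_chr1: int = 60,
    n_chr2: int = 600,
    maf: float = 0.4,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Genotypes with manufactured SNP-QTN LD structure on two chromosomes.

    chr1 carries q causal candidates, each immediately followed by a
    manufactured partner in the regime's r2 band (low: (0.2, 0.5],
    high: (0.9, 1]), plus independent decoys; chr2 holds independent
    fillers. Returns the matrix and the causal-candidate marker indices.
    """
    if regime not in ("low", "high"):
        raise ValueError("regime must be 'low' or 'high'")
    band = (0.2, LOW_LD_THRESHOLD) if regime == "low" else (HIGH_LD_THRESHOLD, 1.0)
    rng = np.random.default_rng(seed)
    cols = []
    chroms = []
    positions = []
    qtn_indices = []
    pos = 0
    for i in range(n_chr1):
        base = rng.binomial(2, maf, size=n).astype(np.int8)
        while base.std() == 0:
            base = rng.binomial(2, maf, size=n).astype(np.int8)
        pos += 1000
        cols.append(base)
        chroms.append("chr1")
        positions.append(pos)
        if i < q:
            qtn_indices.append(len(cols) - 1)
            partner = _make_ld_partner(base, band, maf, rng)
            # halfway position so the partner is the QTN's nearest neighbour
            cols.append(partner)
            chroms.append("chr1")
            positions.append(pos + 500)
    pos = 0
    for _ in range(n_chr2):
        pos += 1000
        cols.append(rng.binomial(2, maf, size=n).astype(np.int8))
        chroms.append("chr2")
        positions.append(pos)
    dosages = np.column_stack(cols)
    p = dosages.shape[1]
    G = GenotypeMatrix(
        dosages=dosages,
        sample_ids=np.array([f"sample{i}" for i in range(n)], dtype=object),
        marker_ids=np.array([f"snp{j}" for j in range(p)], dtype=object),
        chromosome=np.array(chroms, dtype=object),
        position_bp=np.array(positions, dtype=np.int64),
        seed=seed,
    )
    return G, np.asarray(qtn_indices, dtype=np.int64)


def simulate_preset_trait(
    G: GenotypeMatrix,
    qtn_indices: np.ndarray,
    h2: float = 0.7,
    seed: int | None = None,
) -> np.ndarray:
    """Additive equal-effects trait on a fixed QTN set (LD-experiment preset)."""
    rng = np.random.default_rng(seed)
    q = len(qtn_indices)
    beta = rng.normal(0.0, np.sqrt(h2))
    arch = TraitArchitecture(
        qtn_indices=np.asarray(qtn_indices),
        additive_effects=np.full(q, beta / q),
        scheme="equal",
        h2=h2,
        seed=seed,
    )
    g = genetic_value_additive(G, arch)
    g = g - g.mean()
    sd = g.std()
    if sd == 0:
        raise DesignError("degenerate genetic values on the preset QTN set")
    g = g * (np.sqrt(h2) / sd)
    return g + rng.normal(0.0, np.sqrt(1.0 - h2), size=G.n_samples)


def ld_experiment(
    G: GenotypeMatrix,
    qtn_indices: np.ndarray,
    methods,
    regime: str = "low",
    total: int = 500,
    h2: float = 0.7,
    cv_folds: int = 5,
    cv_repeats: int = 1,
    seed: int = 0,
    options: dict | None = None,
) -> tuple[LDExperimentDesign, dict]:
    """Run the QTN-model vs SNP-model comparison; delta_r per method."""
    design, qtn_model, snp_model = build_ld_experiment(
        G, regime=regime, total=total, seed=seed, qtn_set=np.asarray(qtn_indices)
    )
    y = simulate_preset_trait(G, design.qtn_set, h2=h2, seed=seed + 1)
    results = {}
    for tag, markers in (("qtn", qtn_model), ("snp", snp_model)):
        sub = G.subset_markers(markers)
        acc = benchmark_scenario(
            sub, y, methods, scenario_id=f"ld_{regime}_{tag}",
            k=cv_folds, repeats=cv_repeats, seed=seed, options=options,
        )
        results[tag] = acc
    deltas = {}
    for method in methods:
        a = results["qtn"].loc[results["qtn"]["method"] == method, "r"].dropna()
        b = results["snp"].loc[results["snp"]["method"] == method, "r"].dropna()
        deltas[method] = delta_r(a, b)
    return design, {"delta_r": deltas, "tables": results}
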