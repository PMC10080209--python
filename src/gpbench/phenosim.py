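"""Phenotype simulation: additive and additive-x-additive epistatic traits.

A trait is built from q causal markers (QTNs) drawn from a genotype
matrix. Additive genetic values are sum_i beta_i * dosage(QTN_i); the
epistatic class adds a single pairwise interaction term
beta_e * dosage(e1) * dosage(e2) with (e1, e2) drawn from the QTN set.

Effect-size schemes
-------------------
equal        one draw beta ~ N(0, sqrt(h2)), split as beta/q per QTN
large_effect first QTN magnitude fixed at 2*sqrt(h2); the remaining q-1
             effects drawn from N(0, sqrt(h2)) truncated to one SD
gaussian     all q effects i.i.d. N(0, sqrt(h2))

Heritability realization: the centered additive component is rescaled to
empirical variance h2, the centered epistatic component to h2e, and
residuals are drawn with variance 1 - h2 - h2e, so the total phenotypic
variance is ~1 and the target heritabilities are actual data properties
(the literal residual N(0, sqrt(1-h2)) cannot achieve that for arbitrary
effect scales). The realized variance ratio is always recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genosim import GenotypeMatrix

__all__ = [
    "TraitArchitecture",
    "Scenario",
    "PhenotypeSet",
    "EFFECT_SCHEMES",
    "build_scenario_grid",
    "sample_architecture",
    "genetic_value_additive",
    "genetic_value_epistatic",
    "simulate_phenotypes",
    "realized_heritability",
]

EFFECT_SCHEMES = ("equal", "large_effect", "gaussian")

# default grid settings: (p, n) rows, QTN-count rules, heritability columns
GRID_PN = (
    (500, 3000),
    (500, 2000),
    (500, 1000),
    (500, 500),
    (1000, 500),
    (5000, 500),
    (10000, 500),
    (20000, 500),
    (60000, 500),
)
GRID_QTN_RULES = (5, 50, 100, "p/2", "p")
GRID_H2_ADDITIVE = (0.1, 0.4, 0.7)
GRID_H2_EPISTATIC = ((0.7, 0.1), (0.4, 0.4), (0.1, 0.7))


class SimulationError(RuntimeError):
    """Degenerate trait simulation (e.g. zero genetic variance)."""


@dataclass
class TraitArchitecture:
    """Causal configuration of one simulated trait."""

    qtn_indices: np.ndarray
    additive_effects: np.ndarray
    scheme: str
    h2: float
    h2e: float = 0.0
    epistatic_pair: tuple[int, int] | None = None
    epistatic_effect: float | None = None
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.qtn_indices = np.asarray(self.qtn_indices, dtype=np.int64)
        self.additive_effects = np.asarray(self.additive_effects, dtype=float)
        if self.scheme not in EFFECT_SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if len(np.unique(self.qtn_indices)) != len(self.qtn_indices):
            raise ValueError("QTN indices must be distinct")
        if len(self.additive_effects) != len(self.qtn_indices):
            raise ValueError("one additive effect per QTN required")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must lie in (0, 1)")
        if not 0 <= self.h2e < 1 or self.h2 + self.h2e >= 1:
            raise ValueError("need h2e in [0, 1) and h2 + h2e < 1")
        if (self.h2e > 0) != (self.epistatic_pair is not None):
            raise ValueError("epistatic_pair must be present iff h2e > 0")
        if self.epistatic_pair is not None:
            e1, e2 = self.epistatic_pair
            if e1 not in self.qtn_indices or e2 not in self.qtn_indices:
                raise ValueError("epistatic pair must be drawn from the QTN set")

    @property
    def q(self) -> int:
        return len(self.qtn_indices)


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid."""

    p: int
    n: int
    q: int
    h2: float
    h2e: float
    trait_class: str  # "additive" | "epistatic"
    scheme: str
    n_traits: int = 5

    def __post_init__(self) -> None:
        if self.trait_class not in ("additive", "epistatic"):
            raise ValueError(f"unknown trait class {self.trait_class!r}")
        if self.scheme not in EFFECT_SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.q > self.p:
            raise ValueError("q cannot exceed p")
        if self.n_traits < 1:
            raise ValueError("n_traits must be >= 1")

    @property
    def c(self) -> float:
        """Dimensionality ratio p/n."""
        return self.p / self.n

    @property
    def scenario_id(self) -> str:
        tag = f"p{self.p}_n{self.n}_q{self.q}_h{self.h2:g}"
        if self.trait_class == "epistatic":
            tag += f"_he{self.h2e:g}"
        return f"{self.trait_class}_{self.scheme}_{tag}"


@dataclass
class PhenotypeSet:
    """Simulated trait replicates with their generating architectures."""

    values: np.ndarray  # (n, n_traits)
    genetic_values: np.ndarray  # (n, n_traits)
    architectures: list[TraitArchitecture]
    realized_h2: np.ndarray  # (n_traits,)
    seed: int | None = None

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]


def _resolve_q(rule, p: int) -> int:
    if rule == "p/2":
        return p // 2
    if rule == "p":
        return p
    return int(rule)


def build_scenario_grid(
    pn_settings=GRID_PN,
    qtn_rules=GRID_QTN_RULES,
    h2_additive=GRID_H2_ADDITIVE,
    h2_epistatic=GRID_H2_EPISTATIC,
    trait_classes=("additive", "epistatic"),
    schemes=EFFECT_SCHEMES,
    n_traits: int = 5,
) -> list[Scenario]:
    """Enumerate the default simulation grid.

    Defaults give 9 (p, n) settings x 5 QTN counts x 3 heritability
    settings = 135 scenarios per trait class and 135 x 2 classes x 3
    schemes = 810 in total, each carrying ``n_traits`` replicate traits.
    """
    scenarios: list[Scenario] = []
    for scheme in schemes:
        for trait_class in trait_classes:
            herits = (
                [(h, 0.0) for h in h2_additive]
                if trait_class == "additive"
                else list(h2_epistatic)
            )
            for p, n in pn_settings:
                for rule in qtn_rules:
                    q = _resolve_q(rule, p)
                    for h2, h2e in herits:
                        scenarios.append(
                            Scenario(
                                p=p,
                                n=n,
                                q=q,
                                h2=h2,
                                h2e=h2e,
                                trait_class=trait_class,
                                scheme=scheme,
                                n_traits=n_traits,
                            )
                        )
    return scenarios


def sample_architecture(
    G: GenotypeMatrix,
    q: int,
    h2: float,
    h2e: float = 0.0,
    scheme: str = "equal",
    seed: int | None = None,
    qtn_chromosome: str | None = None,
) -> TraitArchitecture:
    """Draw QTN positions and effect sizes for one trait replicate.

    QTN indices are sampled uniformly without replacement, optionally
    restricted to one chromosome. Effects follow the requested scheme;
    the sign of the large effect is drawn uniformly. If ``h2e > 0`` an
    interacting pair is drawn from the QTN set with effect
    beta_e ~ N(0, sqrt(h2e)).
    """
    if h2 <= 0 or h2 >= 1:
        raise ValueError("h2 must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    # effects are drawn before positions so the equal-scheme beta draw is
    # identical across q under a shared seed
    sd = np.sqrt(h2)
    if scheme == "equal":
        beta = rng.normal(0.0, sd)
        effects = np.full(q, beta / q)
    elif scheme == "large_effect":
        sign = rng.choice((-1.0, 1.0))
        rest = []
        while len(rest) < q - 1:  # rejection sampling onto [-sd, sd]
            draw = rng.normal(0.0, sd)
            if abs(draw) <= sd:
                rest.append(draw)
        effects = np.concatenate([[sign * 2.0 * sd], rest])
    elif scheme == "gaussian":
        effects = rng.normal(0.0, sd, size=q)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    if qtn_chromosome is not None:
        candidates = np.flatnonzero(G.chromosome == qtn_chromosome)
    else:
        candidates = np.arange(G.n_markers)
    if q > candidates.size:
        raise ValueError(f"q={q} exceeds available markers ({candidates.size})")
    qtn = np.sort(rng.choice(candidates, size=q, replace=False))

    pair = None
    beta_e = None
    if h2e > 0:
        if q < 2:
            raise ValueError("epistatic traits need q >= 2")
        e1, e2 = rng.choice(qtn, size=2, replace=False)
        pair = (int(e1), int(e2))
        beta_e = float(rng.normal(0.0, np.sqrt(h2e)))
    return TraitArchitecture(
        qtn_indices=qtn,
        additive_effects=effects,
        scheme=scheme,
        h2=h2,
        h2e=h2e,
        epistatic_pair=pair,
        epistatic_effect=beta_e,
        seed=seed,
    )


def genetic_value_additive(G: GenotypeMatrix, arch: TraitArchitecture) -> np.ndarray:
    """Additive genetic value per sample: sum_i beta_i * dosage(QTN_i)."""
    X = G.dosages[:, arch.qtn_indices].astype(float)
    return X @ arch.additive_effects


def genetic_value_epistatic(G: GenotypeMatrix, arch: TraitArchitecture) -> np.ndarray:
    """Additive part plus beta_e * dosage(e1) * dosage(e2)."""
    if arch.epistatic_pair is None:
        raise ValueError("architecture has no epistatic pair")
    e1, e2 = arch.epistatic_pair
    interaction = G.dosages[:, e1].astype(float) * G.dosages[:, e2].astype(float)
    return genetic_value_additive(G, arch) + arch.epistatic_effect * interaction


def _scaled_component(values: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale to the requested empirical variance."""
    centered = values - values.mean()
    v = centered.var()
    if v <= 0:
        raise SimulationError("degenerate genetic component (zero variance)")
    return centered * np.sqrt(target_var / v)


def simulate_phenotypes(
    G: GenotypeMatrix,
    scenario: Scenario,
    seed: int | None = None,
) -> PhenotypeSet:
    """Simulate the scenario's replicate traits on a genotype matrix.

    Each replicate re-draws the full architecture (positions, effects and
    residuals) from a sub-seed derived from ``seed``. Components are
    variance-standardized (see module docstring), so phenotypes have
    variance ~1 with genetic variance h2 (+ h2e for epistatic traits).
    """
    if G.n_samples != scenario.n:
        raise ValueError(
            f"genotype matrix has n={G.n_samples}, scenario expects {scenario.n}"
        )
    if G.n_markers != scenario.p:
        raise ValueError(
            f"genotype matrix has p={G.n_markers}, scenario expects {scenario.p}"
        )
    root = np.random.SeedSequence(seed)
    trait_seeds = [int(s.generate_state(1)[0]) for s in root.spawn(scenario.n_traits)]
    n = scenario.n
    values = np.empty((n, scenario.n_traits))
    genetic = np.empty((n, scenario.n_traits))
    archs: list[TraitArchitecture] = []
    realized = np.empty(scenario.n_traits)
    # an "epistatic" scenario with h2e = 0 degenerates to the additive path
    epistatic = scenario.trait_class == "epistatic" and scenario.h2e > 0
    for t, sub_seed in enumerate(trait_seeds):
        arch = sample_architecture(
            G,
            q=scenario.q,
            h2=scenario.h2,
            h2e=scenario.h2e if epistatic else 0.0,
            scheme=scenario.scheme,
            seed=sub_seed,
        )
        g = _scaled_component(genetic_value_additive(G, arch), scenario.h2)
        if epistatic:
            e1, e2 = arch.epistatic_pair
            inter = G.dosages[:, e1].astype(float) * G.dosages[:, e2].astype(float)
            inter = inter - inter.mean()
            # orthogonalize against the additive component so the two
            # variance targets add up in the total
            inter -= (inter @ g) / (g @ g) * g
            g = g + _scaled_component(inter, scenario.h2e)
        resid_var = 1.0 - scenario.h2 - (scenario.h2e if epistatic else 0.0)
        rng = np.random.default_rng(sub_seed + 1)
        y = g + rng.normal(0.0, np.sqrt(resid_var), size=n)
        values[:, t] = y
        genetic[:, t] = g
        archs.append(arch)
        realized[t] = realized_heritability(g, y)
    return PhenotypeSet(values, genetic, archs, realized, seed=seed)


def realized_heritability(genetic: np.ndarray, phenotype: np.ndarray) -> float:
    """Variance ratio var(genetic) / var(phenotype)."""
    vp = np.var(phenotype)
    if vp == 0:
        raise ValueError("phenotype has zero variance")
    return float(np.var(genetic) / vp)
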