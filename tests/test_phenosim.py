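import numpy as np
import pytest

from gpbench.genosim import simulate_genotypes
from gpbench.phenosim import (
    Scenario,
    TraitArchitecture,
    build_scenario_grid,
    genetic_value_additive,
    genetic_value_epistatic,
    realized_heritability,
    sample_architecture,
    simulate_phenotypes,
)


class TestScenarioGrid:
    def test_135_per_class(self):
        grid = build_scenario_grid(trait_classes=("additive",), schemes=("equal",))
        assert len(grid) == 135

    def test_810_total(self):
        grid = build_scenario_grid()
        assert len(grid) == 810
        assert all(s.n_traits == 5 for s in grid)

    def test_single_cell(self):
        grid = build_scenario_grid(
            pn_settings=((1000, 500),),
            qtn_rules=(5,),
            h2_additive=(0.7,),
            trait_classes=("additive",),
            schemes=("equal",),
        )
        assert len(grid) == 1
        s = grid[0]
        assert (s.p, s.n, s.q, s.h2, s.c) == (1000, 500, 5, 0.7, 2.0)

    def test_qtn_rules_resolve_per_p(self):
        grid = build_scenario_grid(trait_classes=("additive",), schemes=("equal",))
        qs = {s.q for s in grid if s.p == 60000}
        assert qs == {5, 50, 100, 30000, 60000}

    def test_epistatic_heritability_pairs(self):
        grid = build_scenario_grid(trait_classes=("epistatic",), schemes=("equal",))
        pairs = {(s.h2, s.h2e) for s in grid}
        assert pairs == {(0.7, 0.1), (0.4, 0.4), (0.1, 0.7)}
        assert all(s.h2 + s.h2e == pytest.approx(0.8) for s in grid)

    def test_scenario_ids_unique(self):
        grid = build_scenario_grid()
        assert len({s.scenario_id for s in grid}) == 810


class TestSampleArchitecture:
    def test_equal_scheme_identical_effects(self, small_geno):
        arch = sample_architecture(small_geno, q=5, h2=0.7, scheme="equal", seed=1)
        assert np.all(arch.additive_effects == arch.additive_effects[0])

    def test_equal_effect_scales_as_one_over_q(self, small_geno):
        a5 = sample_architecture(small_geno, q=5, h2=0.4, scheme="equal", seed=9)
        a10 = sample_architecture(small_geno, q=10, h2=0.4, scheme="equal", seed=9)
        # same seed draws the same beta; per-QTN effect halves
        assert abs(a5.additive_effects[0]) == pytest.approx(2 * abs(a10.additive_effects[0]))

    def test_large_effect_magnitudes(self, small_geno):
        h2 = 0.4
        for seed in range(20):
            arch = sample_architecture(small_geno, q=50, h2=h2, scheme="large_effect", seed=seed)
            assert abs(arch.additive_effects[0]) == pytest.approx(2 * np.sqrt(h2))
            assert np.all(np.abs(arch.additive_effects[1:]) <= np.sqrt(h2))

    def test_large_effect_value(self, small_geno):
        arch = sample_architecture(small_geno, q=50, h2=0.4, scheme="large_effect", seed=0)
        assert abs(arch.additive_effects[0]) == pytest.approx(1.2649110640673518)

    def test_gaussian_scheme_spread(self, small_geno):
        effects = np.concatenate(
            [
                sample_architecture(small_geno, q=50, h2=0.5, scheme="gaussian", seed=s).additive_effects
                for s in range(20)
            ]
        )
        assert effects.std() == pytest.approx(np.sqrt(0.5), rel=0.1)

    def test_chromosome_restriction(self, small_geno):
        arch = sample_architecture(
            small_geno, q=10, h2=0.5, scheme="equal", seed=3, qtn_chromosome="chr2"
        )
        assert set(small_geno.chromosome[arch.qtn_indices]) == {"chr2"}

    def test_epistatic_pair_from_qtns(self, small_geno):
        arch = sample_architecture(small_geno, q=5, h2=0.4, h2e=0.4, scheme="equal", seed=4)
        assert arch.epistatic_pair is not None
        e1, e2 = arch.epistatic_pair
        assert e1 != e2
        assert e1 in arch.qtn_indices and e2 in arch.qtn_indices

    def test_invalid_inputs(self, small_geno):
        with pytest.raises(ValueError):
            sample_architecture(small_geno, q=10_000, h2=0.5, seed=0)
        with pytest.raises(ValueError):
            sample_architecture(small_geno, q=5, h2=0.0, seed=0)


class TestGeneticValues:
    def test_zero_effects(self, small_geno):
        arch = TraitArchitecture(
            qtn_indices=np.arange(5), additive_effects=np.zeros(5), scheme="equal", h2=0.5
        )
        assert np.all(genetic_value_additive(small_geno, arch) == 0)

    def test_single_qtn_unit_effect(self, small_geno):
        arch = TraitArchitecture(
            qtn_indices=np.array([7]), additive_effects=np.array([1.0]), scheme="gaussian", h2=0.5
        )
        assert np.array_equal(
            genetic_value_additive(small_geno, arch), small_geno.dosages[:, 7].astype(float)
        )

    def test_matches_elementwise_oracle(self, small_geno, rng):
        idx = np.array([2, 5, 11, 30, 41])
        eff = rng.normal(size=5)
        arch = TraitArchitecture(
            qtn_indices=idx, additive_effects=eff, scheme="gaussian", h2=0.5
        )
        g = genetic_value_additive(small_geno, arch)
        for i in range(small_geno.n_samples):
            expected = sum(eff[k] * small_geno.dosages[i, idx[k]] for k in range(5))
            assert g[i] == pytest.approx(expected)

    def test_epistatic_zero_effect_equals_additive(self, small_geno):
        arch = TraitArchitecture(
            qtn_indices=np.array([1, 2]),
            additive_effects=np.array([0.3, -0.2]),
            scheme="gaussian",
            h2=0.4,
            h2e=0.2,
            epistatic_pair=(1, 2),
            epistatic_effect=0.0,
        )
        assert np.allclose(
            genetic_value_epistatic(small_geno, arch), genetic_value_additive(small_geno, arch)
        )

    def test_epistatic_term_zero_when_dosage_zero(self, small_geno):
        arch = TraitArchitecture(
            qtn_indices=np.array([1, 2]),
            additive_effects=np.array([0.0, 0.0]),
            scheme="gaussian",
            h2=0.4,
            h2e=0.2,
            epistatic_pair=(1, 2),
            epistatic_effect=1.5,
        )
        g = genetic_value_epistatic(small_geno, arch)
        zero_rows = small_geno.dosages[:, 1] == 0
        assert np.all(g[zero_rows] == 0)

    def test_epistatic_matches_oracle(self, small_geno, rng):
        arch = TraitArchitecture(
            qtn_indices=np.array([3, 8, 15]),
            additive_effects=rng.normal(size=3),
            scheme="gaussian",
            h2=0.4,
            h2e=0.3,
            epistatic_pair=(8, 15),
            epistatic_effect=0.7,
        )
        g = genetic_value_epistatic(small_geno, arch)
        D = small_geno.dosages.astype(float)
        expected = D[:, [3, 8, 15]] @ arch.additive_effects + 0.7 * D[:, 8] * D[:, 15]
        assert np.allclose(g, expected)

    def test_missing_pair_rejected(self, small_geno):
        arch = TraitArchitecture(
            qtn_indices=np.array([1]), additive_effects=np.array([1.0]), scheme="gaussian", h2=0.5
        )
        with pytest.raises(ValueError):
            genetic_value_epistatic(small_geno, arch)


class TestSimulatePhenotypes:
    def test_realized_h2_recovery(self):
        G = simulate_genotypes(3000, 100, seed=50)
        sc = Scenario(p=100, n=3000, q=5, h2=0.7, h2e=0.0, trait_class="additive",
                      scheme="equal", n_traits=3)
        phen = simulate_phenotypes(G, sc, seed=51)
        assert np.allclose(phen.realized_h2, 0.7, atol=0.05)

    def test_epistatic_component_variances(self):
        G = simulate_genotypes(3000, 100, seed=52)
        sc = Scenario(p=100, n=3000, q=10, h2=0.1, h2e=0.7, trait_class="epistatic",
                      scheme="equal", n_traits=2)
        phen = simulate_phenotypes(G, sc, seed=53)
        resid = phen.values - phen.genetic_values
        assert np.allclose(resid.var(axis=0), 0.2, atol=0.03)
        assert np.allclose(phen.values.var(axis=0), 1.0, atol=0.1)

    def test_unit_phenotype_variance(self, small_geno):
        sc = Scenario(p=120, n=200, q=60, h2=0.4, h2e=0.4, trait_class="epistatic",
                      scheme="gaussian", n_traits=4)
        phen = simulate_phenotypes(small_geno, sc, seed=54)
        assert np.allclose(phen.values.var(axis=0), 1.0, atol=0.25)

    def test_epistatic_h2e_zero_equals_additive_path(self, small_geno):
        kw = dict(p=120, n=200, q=5, h2=0.5, scheme="equal", n_traits=2)
        sc_add = Scenario(h2e=0.0, trait_class="additive", **kw)
        sc_epi = Scenario(h2e=0.0, trait_class="epistatic", **kw)
        a = simulate_phenotypes(small_geno, sc_add, seed=55)
        b = simulate_phenotypes(small_geno, sc_epi, seed=55)
        assert np.array_equal(a.values, b.values)

    def test_replicates_redraw_architecture(self, small_geno):
        sc = Scenario(p=120, n=200, q=5, h2=0.5, h2e=0.0, trait_class="additive",
                      scheme="equal", n_traits=3)
        phen = simulate_phenotypes(small_geno, sc, seed=56)
        qtn_sets = {tuple(a.qtn_indices) for a in phen.architectures}
        assert len(qtn_sets) > 1

    def test_dimension_mismatch_rejected(self, small_geno):
        sc = Scenario(p=120, n=999, q=5, h2=0.5, h2e=0.0, trait_class="additive",
                      scheme="equal")
        with pytest.raises(ValueError):
            simulate_phenotypes(small_geno, sc, seed=0)


class TestRealizedHeritability:
    def test_identity(self, rng):
        y = rng.normal(size=50)
        assert realized_heritability(y, y) == pytest.approx(1.0)

    def test_constant_genetic(self, rng):
        y = rng.normal(size=50)
        assert realized_heritability(np.zeros(50), y) == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            realized_heritability(np.ones(5), np.ones(5))

    def test_recovery_at_target(self):
        G = simulate_genotypes(3000, 50, seed=57)
        sc = Scenario(p=50, n=3000, q=5, h2=0.4, h2e=0.0, trait_class="additive",
                      scheme="gaussian", n_traits=1)
        phen = simulate_phenotypes(G, sc, seed=58)
        r = realized_heritability(phen.genetic_values[:, 0], phen.values[:, 0])
        assert r == pytest.approx(0.4, abs=0.05)


class TestTraitArchitectureInvariants:
    def test_duplicate_qtns_rejected(self):
        with pytest.raises(ValueError):
            TraitArchitecture(
                qtn_indices=np.array([1, 1]),
                additive_effects=np.array([0.1, 0.2]),
                scheme="gaussian",
                h2=0.5,
            )

    def test_heritability_budget(self):
        with pytest.raises(ValueError):
            TraitArchitecture(
                qtn_indices=np.array([1, 2]),
                additive_effects=np.array([0.1, 0.2]),
                scheme="gaussian",
                h2=0.6,
                h2e=0.5,
                epistatic_pair=(1, 2),
                epistatic_effect=0.1,
            )

    def test_pair_requires_h2e(self):
        with pytest.raises(ValueError):
            TraitArchitecture(
                qtn_indices=np.array([1, 2]),
                additive_effects=np.array([0.1, 0.2]),
                scheme="gaussian",
                h2=0.5,
                h2e=0.0,
                epistatic_pair=(1, 2),
                epistatic_effect=0.1,
            )
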