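"""Phenotype-block gLV formalism and the random-community ensemble."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import gutswitch as gs
from gutswitch.glv import (BIMODALITY_CUTOFF, ToyModel, ToyTransition,
                           make_random_toy, simulate_toy, toy_rhs)


def two_species_switch_model(strong_effect=-0.9):
    """Species 0 has a weak phenotype (0) and a strong phenotype (2)
    that suppresses species 1; switching toward the strong phenotype
    activates with E."""
    A = np.array([
        [-1.0, -0.3, -1.0],
        [-0.1, -1.0, strong_effect],
        [-1.0, -0.02, -1.0],
    ])
    return ToyModel(n_species=2, growth=np.array([1.0, 1.0, 1.0]),
                    interactions=A,
                    phenotype_blocks={0: [0, 2], 1: [1]},
                    transitions=[
                        ToyTransition(0, 2, 1.0, 0.5, 8.0, "activating"),
                        ToyTransition(2, 0, 1.0, 0.5, 8.0, "repressing"),
                    ])


class TestMakeRandomToy:
    def test_same_seed_is_identical(self):
        a = make_random_toy(20, seed=7)
        b = make_random_toy(20, seed=7)
        assert np.array_equal(a.interactions, b.interactions)
        assert np.array_equal(a.growth, b.growth)

    def test_switcher_adds_one_phenotype(self):
        model = make_random_toy(50, seed=1)
        assert model.n_phenotypes == 51
        assert model.phenotype_blocks[0] == [0, 50]

    def test_strong_block_mean_exceeds_base(self):
        """The strong phenotype's outgoing interactions have a larger
        mean magnitude than the base block in nearly all draws."""
        wins = 0
        for seed in range(1, 101):
            m = make_random_toy(30, seed=seed)
            strong_col = np.abs(m.interactions[1:30, 30])  # exclude switcher row
            base = np.abs(m.interactions[1:30, 1:30][~np.eye(29, dtype=bool)])
            wins += strong_col.mean() > base.mean()
        assert wins >= 95

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_random_toy(1)
        with pytest.raises(ValueError):
            make_random_toy(10, dist_config=dict(sd=-1.0))


class TestToyRhs:
    def test_extinction_is_absorbing(self):
        model = make_random_toy(10, seed=3)
        assert np.allclose(toy_rhs(np.zeros(11), 0.5, model), 0.0)

    def test_logistic_fixed_point(self):
        model = ToyModel(n_species=1, growth=np.array([0.8]),
                         interactions=np.array([[-0.4]]),
                         phenotype_blocks={0: [0]})
        totals, ok = simulate_toy(model, init=np.array([0.01]), t_end=200.0)
        assert ok
        assert totals[0] == pytest.approx(0.8 / 0.4, rel=1e-4)

    def test_switching_flux_at_threshold(self):
        model = two_species_switch_model()
        model.E = 0.5  # Hill midpoint: flux = k * 0.5 * x_source
        x = np.array([2.0, 0.0, 0.0])
        dx = toy_rhs(x, model.E, model)
        growth_term = 2.0 * (1.0 - 1.0 * 2.0)
        assert dx[0] == pytest.approx(growth_term - 1.0 * 0.5 * 2.0)
        assert dx[2] == pytest.approx(1.0 * 0.5 * 2.0)

    def test_non_finite_input_rejected(self):
        model = make_random_toy(5, seed=0)
        with pytest.raises(ValueError):
            toy_rhs(np.full(6, np.nan), 0.5, model)


class TestSimulateToy:
    def test_reduces_to_plain_glv_without_switching(self):
        """Single-phenotype species with zero switching rates must match
        a direct gLV integration on the same (r, A)."""
        model = make_random_toy(12, seed=5,
                                switcher_config=dict(strength=1.0,
                                                     received_scale=1.0,
                                                     k_switch=0.0))
        totals, ok = simulate_toy(model, t_end=800.0)
        assert ok

        r, A = model.growth, model.interactions
        sol = solve_ivp(lambda t, x: np.maximum(x, 0) * (r + A @ np.maximum(x, 0)),
                        (0, 800.0), np.full(13, 0.05),
                        method="LSODA", rtol=1e-7, atol=1e-10)
        x = np.clip(sol.y[:, -1], 0.0, None)
        x[x < 1e-6] = 0.0
        direct = model.species_totals(x)
        np.testing.assert_allclose(totals, direct, rtol=1e-4, atol=1e-6)

    def test_environment_flips_dominance(self):
        """Sweeping E across the Hill threshold flips which species
        dominates the two-species hand-built community."""
        model = two_species_switch_model()
        model.E = 0.1
        low, ok_low = simulate_toy(model, t_end=400.0)
        model.E = 0.9
        high, ok_high = simulate_toy(model, t_end=400.0)
        assert ok_low and ok_high
        assert low[1] > low[0]     # weak phenotype: species 1 wins
        assert high[0] > high[1]   # strong phenotype: switcher wins

    def test_all_zero_init_stays_zero(self):
        model = make_random_toy(8, seed=2)
        totals, ok = simulate_toy(model, init=np.zeros(9))
        assert ok
        assert np.all(totals == 0.0)

    def test_negative_init_rejected(self):
        model = make_random_toy(8, seed=2)
        with pytest.raises(ValueError):
            simulate_toy(model, init=-np.ones(9))


class TestEnsemble:
    def test_shape_and_reproducibility(self):
        a = gs.ensemble(20, 10, "strong", seed=4, t_end=600.0)
        b = gs.ensemble(20, 10, "strong", seed=4, t_end=600.0)
        assert a.abundances.shape[1] == 10
        assert np.array_equal(a.abundances, b.abundances)
        assert np.array_equal(a.E_values, b.E_values)
        assert 0.5 <= a.convergence_fraction <= 1.0

    def test_too_few_communities_rejected(self):
        with pytest.raises(ValueError):
            gs.ensemble(1, 10, "strong", seed=1)
        with pytest.raises(ValueError):
            gs.ensemble(10, 10, "weird", seed=1)


class TestBimodalityCoefficient:
    def test_analytic_benchmarks(self, rng):
        n = 100_000
        two_point = rng.choice([0.0, 1.0], size=n)
        uniform = rng.uniform(size=n)
        normal = rng.normal(size=n)
        assert gs.bimodality_coefficient(two_point) == pytest.approx(1.0, abs=0.02)
        assert gs.bimodality_coefficient(uniform) == pytest.approx(1 / 1.8, abs=0.02)
        assert gs.bimodality_coefficient(normal) == pytest.approx(1 / 3, abs=0.02)
        assert BIMODALITY_CUTOFF == pytest.approx(1 / 1.8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            gs.bimodality_coefficient([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            gs.bimodality_coefficient([1.0, 2.0, 3.0])


class TestEnterotypeProjection:
    def test_two_identical_blocks_have_perfect_silhouette(self):
        X = np.vstack([np.tile([5.0, 1.0, 1.0], (10, 1)),
                       np.tile([1.0, 1.0, 5.0], (10, 1))])
        ens = gs.ToyEnsemble(abundances=X, E_values=np.zeros(20),
                             switcher_id=0, regime="strong")
        _, labels, sil, _ = gs.enterotype_projection(ens)
        assert sil == pytest.approx(1.0)
        assert len(set(labels)) == 2

    def test_degenerate_matrix_rejected(self):
        X = np.tile([1.0, 2.0, 3.0], (15, 1))
        ens = gs.ToyEnsemble(abundances=X, E_values=np.zeros(15),
                             switcher_id=0, regime="null")
        with pytest.raises(ValueError):
            gs.enterotype_projection(ens)

    def test_too_few_communities_rejected(self):
        ens = gs.ToyEnsemble(abundances=np.eye(4), E_values=np.zeros(4),
                             switcher_id=0, regime="null")
        with pytest.raises(ValueError):
            gs.enterotype_projection(ens)
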