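import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from partbias import participation, popsim
from partbias.participation import LOGISTIC_VARIANCE


class TestEffectDrawing:
    def test_linear_predictor_variance_identity(self, rng):
        """h2 = 0.5 puts Var(eta) at exactly pi^2/3, and the liability
        identity h2 = V/(V + pi^2/3) is recovered analytically."""
        mafs = rng.uniform(0.05, 0.5, 200)
        b_f, b_m = participation.draw_participation_effects(
            mafs, 0.5, 0.3, rng=rng
        )
        var_f = np.sum(2 * mafs * (1 - mafs) * b_f**2)
        var_m = np.sum(2 * mafs * (1 - mafs) * b_m**2)
        assert abs(var_f - LOGISTIC_VARIANCE) < 1e-10
        for var, h2 in ((var_f, 0.5), (var_m, 0.3)):
            assert abs(var / (var + LOGISTIC_VARIANCE) - h2) < 1e-6

    def test_zero_heritability_zero_effects(self, rng):
        b_f, b_m = participation.draw_participation_effects(
            np.array([0.2, 0.4]), 0.0, 0.0, rng=rng
        )
        assert np.all(b_f == 0) and np.all(b_m == 0)

    def test_sex_independent_vectors_identical(self, rng):
        mafs = rng.uniform(0.1, 0.5, 50)
        b_f, b_m = participation.draw_participation_effects(
            mafs, 0.2, 0.2, scenario="sex_independent", correlation=0.0, rng=rng
        )
        assert np.array_equal(b_f, b_m)

    def test_between_sex_effect_correlation(self, rng):
        mafs = rng.uniform(0.1, 0.5, 10_000)
        b_f, b_m = participation.draw_participation_effects(
            mafs, 0.3, 0.3, scenario="sex_differential", correlation=0.0, rng=rng
        )
        assert abs(np.corrcoef(b_f, b_m)[0, 1]) < 0.04

    def test_h2_of_one_rejected(self):
        with pytest.raises(ValueError):
            participation.draw_participation_effects(np.array([0.2]), 1.0, 0.0)


class TestCalibration:
    def test_closed_form_intercepts(self):
        zeros = np.zeros(100)
        a_f, a_m = participation.calibrate_intercepts(zeros, zeros, 0.05, 0.5)
        assert abs(a_f - (-2.9444)) < 1e-4
        assert abs(a_m) < 1e-10

    def test_matches_grid_search(self, rng):
        """Root-found intercept agrees with a fine grid search over alpha."""
        eta = rng.normal(0, 1, 2_000)
        target = 0.05
        a, _ = participation.calibrate_intercepts(eta, np.zeros(1), target, 0.5)
        grid = np.linspace(-6, 0, 60_001)
        rates = expit(grid[:, None] + eta[None, :]).mean(axis=1)
        a_grid = grid[np.argmin(np.abs(rates - target))]
        assert abs(a - a_grid) < 5e-4  # within one grid step
        assert abs(expit(a + eta).mean() - target) < 1e-6

    def test_full_participation_intercept_infinite(self):
        a_f, a_m = participation.calibrate_intercepts(
            np.zeros(10), np.zeros(10), 1.0, 1.0
        )
        assert np.isposinf(a_f) and np.isposinf(a_m)

    @pytest.mark.parametrize("pi", [0.0, -0.1, 1.5])
    def test_invalid_rate_rejected(self, pi):
        with pytest.raises(ValueError):
            participation.calibrate_intercepts(np.zeros(5), np.zeros(5), pi, 0.5)

    @given(
        pi=st.floats(0.005, 0.995),
        scale=st.floats(0.0, 2.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_calibration_hits_target_and_is_idempotent(self, pi, scale, seed):
        eta = np.random.default_rng(seed).normal(0, scale, 2000)
        a, _ = participation.calibrate_intercepts(eta, np.zeros(1), pi, 0.5)
        achieved = float(expit(a + eta).mean())
        assert abs(achieved - pi) < 1e-4
        a2, _ = participation.calibrate_intercepts(eta, np.zeros(1), achieved, 0.5)
        assert abs(a2 - a) < 1e-6


class TestSimulateParticipation:
    def test_pure_bernoulli_rates(self):
        cfg = popsim.PopulationConfig(50_000, 5, maf=0.3, seed=20)
        cohort = popsim.simulate_cohort(cfg)
        model = participation.ParticipationModel(
            0.1, 0.1, np.zeros(5), np.zeros(5), scenario="sex_independent"
        )
        model = participation.calibrate_model(cohort, model)
        _, summary = participation.simulate_participation(cohort, model, seed=21)
        se = 4 * np.sqrt(0.1 * 0.9 / (cfg.n_individuals / 2))
        assert abs(summary.realized_rate_female - 0.1) < se
        assert abs(summary.realized_rate_male - 0.1) < se
        assert abs(summary.rate_difference) < 2 * se
        assert summary.rate_difference == (
            summary.realized_rate_male - summary.realized_rate_female
        )

    def test_full_participation_includes_everyone(self):
        cfg = popsim.PopulationConfig(2_000, 3, maf=0.3, seed=22)
        cohort = popsim.simulate_cohort(cfg)
        model = participation.ParticipationModel(
            1.0, 1.0, np.zeros(3), np.zeros(3), scenario="sex_independent"
        )
        model = participation.calibrate_model(cohort, model)
        part, _ = participation.simulate_participation(cohort, model, seed=23)
        assert part.all()
        sub = cohort.participants()
        assert np.array_equal(sub.genotypes, cohort.genotypes)

    def test_cell_probabilities_match_enumeration(self):
        """Single-variant participation probabilities agree with the exact
        expit over all 6 (genotype, sex) cells."""
        n, maf, pi = 400_000, 0.3, 0.01
        cfg = popsim.PopulationConfig(n, 1, maf=maf, seed=24)
        cohort = popsim.simulate_cohort(cfg)
        b_m = np.array([0.2])
        model = participation.ParticipationModel(
            pi, pi, np.zeros(1), b_m, scenario="sex_differential"
        )
        model = participation.calibrate_model(cohort, model)
        part, _ = participation.simulate_participation(cohort, model, seed=25)
        for s, alpha, b in ((0, model.alpha_female, 0.0), (1, model.alpha_male, 0.2)):
            for g in (0, 1, 2):
                cell = (cohort.sex == s) & (cohort.genotypes[:, 0] == g)
                p_exact = expit(alpha + b * (g - 2 * maf))
                se = np.sqrt(p_exact * (1 - p_exact) / cell.sum())
                assert abs(part[cell].mean() - p_exact) < 4 * se

    def test_symmetric_model_shares_one_intercept(self):
        cfg = popsim.PopulationConfig(5_000, 10, maf=0.3, seed=26)
        cohort = popsim.simulate_cohort(cfg)
        b_f, b_m = participation.draw_participation_effects(
            cohort.mafs, 0.2, 0.2, scenario="sex_independent", seed=27
        )
        model = participation.ParticipationModel(
            0.05, 0.05, b_f, b_m, scenario="sex_independent"
        )
        model = participation.calibrate_model(cohort, model)
        assert model.alpha_female == model.alpha_male

    def test_uncalibrated_model_rejected(self):
        cfg = popsim.PopulationConfig(100, 2, maf=0.3, seed=28)
        cohort = popsim.simulate_cohort(cfg)
        model = participation.ParticipationModel(
            0.5, 0.5, np.zeros(2), np.zeros(2), scenario="sex_independent"
        )
        with pytest.raises(RuntimeError):
            participation.simulate_participation(cohort, model, seed=29)

    def test_sex_independent_scenario_enforces_equal_effects(self):
        with pytest.raises(ValueError):
            participation.ParticipationModel(
                0.1, 0.1, np.zeros(2), np.ones(2), scenario="sex_independent"
            )
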