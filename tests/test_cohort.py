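"""Hazards, cohort integration, and alive-conditioned summaries."""

import numpy as np
import pytest
from scipy.linalg import expm

from mmnathist.cohort import (AgeGrid, CohortTrajectory, ExtinctCohortError,
                              MortalitySchedule, bin_weighted_summary,
                              integrate_cohort, mgus_rate, mm_rate,
                              state_incidence, state_prevalence)
from mmnathist.params import ParameterVector
from mmnathist.strata import STRATA, Gender, StratumKey

from conftest import plausible_parameters

MALE_NHW, FEMALE_NHW, MALE_NHB, FEMALE_NHB = STRATA


class TestHazards:
    def test_zero_parameters_give_unit_rate(self):
        p = ParameterVector()
        assert mgus_rate(p, 50.0, MALE_NHW) == pytest.approx(1.0)
        assert mm_rate(p, 37.0, MALE_NHW) == pytest.approx(1.0)

    def test_exponent_arithmetic(self):
        p = ParameterVector(gamma_mgus=-6.0, beta_mgus_a=0.05)
        assert mgus_rate(p, 60.0, MALE_NHW) == pytest.approx(np.exp(-3.0), rel=1e-12)

    def test_female_multiplier_is_age_independent(self):
        p = ParameterVector(gamma_mgus=-9.0, beta_mgus_a=0.05,
                            beta_mgus_s=np.log(0.59), beta_mgus_r=np.log(2.0),
                            gamma_mm=-8.0, beta_mm_a=0.1, beta_mm_a2=-0.001,
                            beta_mm_s=np.log(1.1), beta_mm_r=np.log(1.2))
        for age in (0.0, 42.5, 60.0, 85.0):
            assert mgus_rate(p, age, FEMALE_NHW) / mgus_rate(p, age, MALE_NHW) \
                == pytest.approx(0.59, rel=1e-12)
            assert mgus_rate(p, age, MALE_NHB) / mgus_rate(p, age, MALE_NHW) \
                == pytest.approx(2.0, rel=1e-12)
            assert mm_rate(p, age, FEMALE_NHW) / mm_rate(p, age, MALE_NHW) \
                == pytest.approx(1.1, rel=1e-12)
            assert mm_rate(p, age, MALE_NHB) / mm_rate(p, age, MALE_NHW) \
                == pytest.approx(1.2, rel=1e-12)

    def test_quadratic_rate_peaks_at_vertex(self):
        p = ParameterVector(beta_mm_a=0.142, beta_mm_a2=-0.001)
        vertex = -p.beta_mm_a / (2 * p.beta_mm_a2)
        assert vertex == pytest.approx(71.0)
        ages = np.linspace(0, 120, 500)
        rates = mm_rate(p, ages, MALE_NHW)
        assert np.all(mm_rate(p, vertex, MALE_NHW) >= rates)

    def test_negative_age_rejected(self):
        p = ParameterVector()
        with pytest.raises(ValueError):
            mgus_rate(p, -1.0, MALE_NHW)
        with pytest.raises(ValueError):
            mm_rate(p, -0.5, MALE_NHW)


class TestIntegrateCohort:
    def test_no_flows_stays_healthy(self):
        p = ParameterVector(gamma_mgus=-np.inf, gamma_mm=-np.inf)
        # -inf intercepts give exactly zero hazards
        traj = integrate_cohort(p, MortalitySchedule.zero(), AgeGrid(), MALE_NHW)
        assert np.all(traj.p_h == 1.0)
        assert np.all(traj.p_d == 0.0)

    def test_constant_onset_rate_matches_exponential(self):
        lam = 0.01
        p = ParameterVector(gamma_mgus=np.log(lam), gamma_mm=-np.inf)
        grid = AgeGrid(0, 100, 0.1)
        traj = integrate_cohort(p, MortalitySchedule.zero(), grid, MALE_NHW)
        ages = traj.ages
        assert np.allclose(traj.p_mgus, 1.0 - np.exp(-lam * ages), atol=1e-9)
        assert traj.at(100.0)[1] == pytest.approx(1 - np.exp(-1.0), abs=1e-9)

    def test_constant_rates_match_matrix_exponential(self):
        """With all rates age-constant the system is a linear ODE with
        constant generator; expm is the closed-form oracle."""
        lam1, lam2, mu_h, mu_g, mu_m = 0.02, 0.05, 0.01, 0.015, 0.3
        p = ParameterVector(gamma_mgus=np.log(lam1), gamma_mm=np.log(lam2))
        mort = MortalitySchedule(
            mu_h={(a, s): mu_h for a in range(100) for s in STRATA},
            mgus_multiplier={Gender.male: mu_g / mu_h, Gender.female: mu_g / mu_h},
            mu_mm={s: mu_m for s in STRATA})
        traj = integrate_cohort(p, mort, AgeGrid(), MALE_NHW)
        A = np.array([
            [-(lam1 + mu_h), 0.0, 0.0, 0.0],
            [lam1, -(lam2 + mu_g), 0.0, 0.0],
            [0.0, lam2, -mu_m, 0.0],
            [mu_h, mu_g, mu_m, 0.0],
        ])
        for age in (1.0, 25.0, 60.0, 99.0):
            exact = expm(A * age) @ np.array([1.0, 0.0, 0.0, 0.0])
            assert np.allclose(traj.at(age), exact, atol=1e-6)

    def test_converges_under_step_refinement(self, mortality):
        rng = np.random.default_rng(11)
        p = plausible_parameters(rng)
        coarse = integrate_cohort(p, mortality, AgeGrid(step=0.1), MALE_NHB)
        fine = integrate_cohort(p, mortality, AgeGrid(step=0.01), MALE_NHB)
        for age in range(0, 100, 7):
            assert np.allclose(coarse.at(age), fine.at(age), atol=1e-6)

    def test_non_normalized_initial_state_rejected(self, mortality):
        with pytest.raises(ValueError):
            integrate_cohort(ParameterVector(), mortality, AgeGrid(), MALE_NHW,
                             initial_state=[0.5, 0.4, 0.0, 0.0])
        with pytest.raises(ValueError):
            integrate_cohort(ParameterVector(), mortality, AgeGrid(), MALE_NHW,
                             initial_state=[1.2, -0.2, 0.0, 0.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_and_monotonicity(self, mortality, seed):
        """Proportions sum to one and death only accumulates, for random
        plausible parameters in every stratum."""
        p = plausible_parameters(np.random.default_rng(seed))
        for st in STRATA:
            traj = integrate_cohort(p, mortality, AgeGrid(), st)
            total = traj.p_h + traj.p_mgus + traj.p_mm + traj.p_d
            assert np.max(np.abs(total - 1.0)) < 1e-9
            assert np.all(np.diff(traj.p_d) >= -1e-15)
            assert np.all(np.diff(traj.p_h) <= 1e-15)
            assert np.all((traj.p_h >= 0) & (traj.p_h <= 1))
            assert np.all((traj.p_mgus >= 0) & (traj.p_mgus <= 1))


def _manual_trajectory(p_h, p_mgus, p_mm, p_d, grid=None):
    grid = grid or AgeGrid(0, 1, 1.0)
    n = grid.n_steps + 1
    return CohortTrajectory(grid=grid, stratum=MALE_NHW,
                            p_h=np.full(n, p_h), p_mgus=np.full(n, p_mgus),
                            p_mm=np.full(n, p_mm), p_d=np.full(n, p_d))


class TestAliveConditioning:
    def test_no_deaths_prevalence_equals_proportions(self):
        traj = _manual_trajectory(0.9, 0.08, 0.02, 0.0)
        assert state_prevalence(traj, 1.0) == pytest.approx((0.9, 0.08, 0.02))

    def test_division_by_survivors(self):
        traj = _manual_trajectory(0.35, 0.1, 0.05, 0.5)
        p_h, p_mgus, p_mm = state_prevalence(traj, 1.0)
        assert (p_mgus, p_mm) == pytest.approx((0.2, 0.1))
        assert p_h == pytest.approx(0.7)

    def test_prevalences_sum_to_one_exactly(self, mortality):
        p = plausible_parameters(np.random.default_rng(3))
        traj = integrate_cohort(p, mortality, AgeGrid(), FEMALE_NHB)
        for age in (0.0, 30.0, 65.0, 99.0):
            assert sum(state_prevalence(traj, age)) == pytest.approx(1.0, abs=1e-15)

    def test_extinct_cohort_raises(self):
        traj = _manual_trajectory(0.0, 0.0, 0.0, 1.0)
        with pytest.raises(ExtinctCohortError):
            state_prevalence(traj, 1.0)

    def test_incidence_is_hazard_times_prevalence(self, mortality):
        p = plausible_parameters(np.random.default_rng(8))
        traj = integrate_cohort(p, mortality, AgeGrid(), MALE_NHB)
        rng = np.random.default_rng(0)
        for age in rng.integers(1, 99, size=10).astype(float):
            i_mgus, i_mm = state_incidence(traj, p, mortality, age)
            p_h, p_mgus, _ = state_prevalence(traj, age)
            assert i_mgus == pytest.approx(mgus_rate(p, age, MALE_NHB) * p_h, rel=1e-12)
            assert i_mm == pytest.approx(mm_rate(p, age, MALE_NHB) * p_mgus, rel=1e-12)
            assert i_mgus >= 0 and i_mm >= 0

    def test_no_at_risk_pool_means_no_incidence(self):
        traj = _manual_trajectory(1.0, 0.0, 0.0, 0.0)
        mort = MortalitySchedule.zero()
        _, i_mm = state_incidence(traj, ParameterVector(), mort, 1.0)
        assert i_mm == 0.0


class _FlatPopulation:
    def __init__(self, weights):
        self.weights = weights

    def count(self, age, stratum):
        return self.weights.get(age, 0.0)


class TestBinWeightedSummary:
    def test_equal_weights_give_arithmetic_mean(self):
        values = {a: float(a) for a in range(50, 55)}
        pop = _FlatPopulation({a: 7.0 for a in range(50, 55)})
        assert bin_weighted_summary(values, pop, (50, 54), MALE_NHW) \
            == pytest.approx(np.mean(list(values.values())))

    def test_weighted_mean(self):
        pop = _FlatPopulation({60: 1.0, 61: 3.0})
        assert bin_weighted_summary({60: 0.1, 61: 0.2}, pop, (60, 61), MALE_NHW) \
            == pytest.approx(0.175)

    def test_single_age_bin_is_identity(self):
        pop = _FlatPopulation({70: 123.0})
        assert bin_weighted_summary({70: 0.42}, pop, (70, 70), MALE_NHW) == 0.42

    def test_zero_population_rejected(self):
        pop = _FlatPopulation({})
        with pytest.raises(ValueError):
            bin_weighted_summary({50: 0.1}, pop, (50, 50), MALE_NHW)


class TestMortalitySchedule:
    def test_ages_beyond_table_reuse_last_value(self, mortality):
        last = mortality.mu_h_at(99, MALE_NHW)
        assert mortality.mu_h_at(105.0, MALE_NHW) == last
        assert mortality.mu_h_at(200.0, MALE_NHW) == last

    def test_mgus_mortality_is_gender_multiple(self, mortality):
        for st in STRATA:
            mult = 1.25 if st.gender is Gender.male else 1.11
            assert mortality.mu_mgus_at(60.0, st) \
                == pytest.approx(mult * mortality.mu_h_at(60.0, st))

    def test_grid_step_must_divide_one_year(self):
        with pytest.raises(ValueError):
            AgeGrid(step=0.3)
        AgeGrid(step=0.25)  # exact divisor is fine
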