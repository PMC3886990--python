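"""Imperfect-sorting scenarios and simulated-annealing fits."""

import numpy as np
import pytest

from cscdyn import (AnnealSchedule, KineticParameters, ParameterError,
                    PopulationState, SortingScenario, apply_sorting_error,
                    cross_evaluate, generate_time_course, objective,
                    reduced_proportion_rate, simulated_annealing_fit)
from cscdyn.fitting import _anneal


class TestSortingError:
    def test_contaminated_csc_sort(self):
        state = apply_sorting_error(SortingScenario("CSC", 1000, 2.0))
        assert state.csc_count == pytest.approx(980.0)
        assert state.nscc_counts[0] == pytest.approx(20.0)
        assert np.all(state.nscc_counts[1:] == 0.0)

    def test_zero_error_is_pure(self):
        state = apply_sorting_error(SortingScenario("NSCC", 500, 0.0))
        assert state.csc_count == 0.0
        assert state.nscc_total == pytest.approx(500.0)

    def test_nominal_nscc_initial_proportion(self):
        state = apply_sorting_error(SortingScenario("NSCC", 1000, 2.0))
        assert state.csc_count / state.total == pytest.approx(0.02)

    def test_invalid_theta(self):
        with pytest.raises(ParameterError):
            SortingScenario("CSC", 1000, 120.0)


class TestObjective:
    def test_self_consistency(self):
        times = np.arange(0.0, 20.0, 2.0)
        initial = apply_sorting_error(SortingScenario("CSC", 1000, 2.0))
        candidate = (0.9, 0.5, 0.6)
        params = KineticParameters(
            division_probs=__import__("cscdyn").DivisionProbabilities.from_e(0.6),
            k_transition=0.0, k_nscc_division=0.5, k_csc_mitosis=0.9)
        course = generate_time_course(params, initial, times, noise_sigma=0.0)
        assert objective(candidate, times, course.observed_proportions,
                         initial) < 1e-12

    def test_constant_zero_data_gives_sum_of_squared_proportions(self,
                                                                 default_params):
        times = np.arange(1.0, 6.0, 1.0)
        initial = PopulationState.pure_csc(1000.0)
        course = generate_time_course(default_params, initial, times,
                                      noise_sigma=0.0)
        obj = objective((default_params.k_csc_mitosis,
                         default_params.k_nscc_division, default_params.e),
                        times, np.zeros_like(times), initial,
                        k_transition=default_params.k_transition)
        assert obj == pytest.approx(np.sum(course.true_proportions ** 2), rel=1e-9)

    def test_noise_floor(self, default_params):
        """With matched parameters the objective averages n * sigma^2."""
        times = np.arange(0.0, 20.0, 2.0)
        initial = apply_sorting_error(SortingScenario("CSC", 1000, 2.0))
        sigma = 0.02
        rng = np.random.default_rng(31)
        objs = []
        for _ in range(60):
            course = generate_time_course(default_params, initial, times,
                                          sigma, rng)
            objs.append(objective(
                (default_params.k_csc_mitosis, default_params.k_nscc_division,
                 default_params.e), times, course.observed_proportions, initial,
                k_transition=default_params.k_transition))
        assert np.mean(objs) == pytest.approx(times.size * sigma ** 2, rel=0.25)


class TestAnnealer:
    def test_convex_smoke(self):
        """The chain settles into the global minimum of a 1-D parabola."""
        schedule = AnnealSchedule(n_proposals=3000, cool_every=30,
                                  bounds=((0.01, 3.0),))
        rng = np.random.default_rng(5)
        best_f, best_x = _anneal(lambda x: (x[0] - 2.0) ** 2,
                                 np.array([[0.01, 3.0]]), schedule, rng)
        assert best_x[0] == pytest.approx(2.0, abs=0.02)
        assert best_f < 5e-4

    def test_determinism_under_seed(self, default_params):
        times = np.arange(0.0, 12.0, 2.0)
        initial = apply_sorting_error(SortingScenario("CSC", 1000, 2.0))
        course = generate_time_course(default_params, initial, times, 0.02, seed=8)
        schedule = AnnealSchedule(n_proposals=120)
        kw = dict(scenario=SortingScenario("CSC", 1000, 2.0), schedule=schedule,
                  n_fits=3, seed=99)
        a = simulated_annealing_fit(times, course.observed_proportions, **kw)
        b = simulated_annealing_fit(times, course.observed_proportions, **kw)
        assert [(f.k_csc_mitosis, f.objective) for f in a] == \
               [(f.k_csc_mitosis, f.objective) for f in b]

    def test_threshold_infinite_accepts_everything(self, default_params):
        times = np.arange(0.0, 12.0, 2.0)
        initial = apply_sorting_error(SortingScenario("CSC", 1000, 2.0))
        course = generate_time_course(default_params, initial, times, 0.02, seed=8)
        schedule = AnnealSchedule(n_proposals=50, threshold=np.inf)
        fits = simulated_annealing_fit(times, course.observed_proportions,
                                       SortingScenario("CSC", 1000, 2.0),
                                       schedule, n_fits=4, seed=1)
        assert len(fits) == 4 and all(f.accepted for f in fits)

    def test_identifiable_combinations_recovered(self):
        """Noiseless hierarchy-only data pins the reduced-dynamics combinations.

        (K_C, K_N, e) individually sit on a near-flat objective ridge, so the
        fit is judged on the identifiable quantities K_C*e - K_N and
        K_C - K_N, and on trajectory agreement.
        """
        truth = KineticParameters(k_transition=0.0)
        times = np.arange(0.0, 26.5, 2.0)
        initial = apply_sorting_error(SortingScenario("CSC", 1000, 0.0))
        course = generate_time_course(truth, initial, times, noise_sigma=0.0)
        data = course.observed_proportions
        schedule = AnnealSchedule(n_proposals=4000)
        fits = simulated_annealing_fit(times, data,
                                       SortingScenario("CSC", 1000, 0.0),
                                       schedule, n_fits=6, seed=3)
        best = min(fits, key=lambda f: f.objective)
        c_hat = best.k_csc_mitosis * best.e_effective - best.k_nscc_division
        dk_hat = best.k_csc_mitosis - best.k_nscc_division
        c_true = truth.k_csc_mitosis * truth.e - truth.k_nscc_division
        dk_true = truth.k_csc_mitosis - truth.k_nscc_division
        assert c_hat == pytest.approx(c_true, abs=0.05 * abs(c_true) + 0.005)
        assert dk_hat == pytest.approx(dk_true, abs=0.05 * abs(dk_true) + 0.005)
        assert best.objective < 1e-4  # trajectory reproduced


class TestEarlyTimeArgument:
    def test_hierarchy_growth_of_rare_csc_fraction_is_slow(self):
        """With K_T=0 the early relative growth of R is (K_C e - K_N)(1 - R)."""
        params = KineticParameters(k_transition=0.0)
        r0 = 0.02
        rate = reduced_proportion_rate(r0, params)
        k_c, k_n, e = (params.k_csc_mitosis, params.k_nscc_division, params.e)
        exact = r0 * ((k_c * e - k_n) - r0 * (k_c - k_n))
        assert rate == pytest.approx(exact, rel=1e-12)
        # leading-order form R (K_C e - K_N)(1 - R) holds to ~10% at R = 0.02
        assert rate == pytest.approx(r0 * (k_c * e - k_n) * (1 - r0), rel=0.15)
        # reaching dR/dt ~ 0.1/day at R=0.02 would need K_C e - K_N > 5
        assert abs(rate) < 0.01

    def test_transition_dominates_early_rise(self, default_params):
        """With K_T=0.269 the early dR/dt is approximately K_T."""
        rate = reduced_proportion_rate(0.02, default_params)
        assert rate == pytest.approx(default_params.k_transition, rel=0.15)


@pytest.fixture(scope="module")
def verdict_setup(default_params):
    times = np.arange(0.0, 26.5, 2.0)
    theta = 2.0
    rng = np.random.default_rng(17)
    csc0 = apply_sorting_error(SortingScenario("CSC", 1000, theta))
    nscc0 = apply_sorting_error(SortingScenario("NSCC", 1000, theta))
    csc_data = generate_time_course(default_params, csc0, times, 0.02,
                                    rng).observed_proportions
    nscc_data = generate_time_course(default_params, nscc0, times, 0.02,
                                     rng).observed_proportions
    schedule = AnnealSchedule(n_proposals=400, cool_every=25)
    fits = simulated_annealing_fit(times, csc_data,
                                   SortingScenario("CSC", 1000, theta),
                                   schedule, n_fits=10, seed=11)
    return times, theta, nscc_data, schedule, fits


class TestCrossEvaluation:
    def test_hierarchy_cannot_explain_nscc_data(self, verdict_setup):
        times, theta, nscc_data, schedule, fits = verdict_setup
        assert any(f.accepted for f in fits)
        table, verdict = cross_evaluate(
            fits, times, nscc_data, SortingScenario("NSCC", 1000, theta),
            threshold=schedule.threshold_for(times.size))
        assert verdict == "hierarchy-insufficient"
        assert table.nscc_objective.min() > schedule.threshold_for(times.size)

    def test_fits_pass_on_their_own_data(self, verdict_setup, default_params):
        times, theta, _, schedule, fits = verdict_setup
        initial = apply_sorting_error(SortingScenario("CSC", 1000, theta))
        thr = schedule.threshold_for(times.size)
        for f in fits:
            if f.accepted:
                assert f.objective < thr

    def test_short_lifespan_reaches_equilibrium_sooner(self):
        """A hierarchy-only fit needs M ~ 5 to mimic the fast NSCC rise."""
        times = np.array([10.0])
        r_at_10 = {}
        for m in (5, 50):
            params = KineticParameters(k_transition=0.0, k_nscc_division=0.5,
                                       lifespan_generations=m)
            initial = apply_sorting_error(SortingScenario("NSCC", 1000, 2.0), m)
            course = generate_time_course(params, initial, times, 0.0)
            r_at_10[m] = course.true_proportions[0]
        assert r_at_10[5] > r_at_10[50]

    def test_empty_accepted_set_raises(self, default_params):
        times = np.arange(0.0, 10.0, 2.0)
        from cscdyn import FitResult
        bad = [FitResult(1.0, 0.5, 0.5, 10.0, False, 0)]
        with pytest.raises(ParameterError):
            cross_evaluate(bad, times, np.zeros_like(times),
                           SortingScenario("NSCC", 1000, 2.0), threshold=0.01)
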