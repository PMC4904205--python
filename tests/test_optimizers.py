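import math

import numpy as np
import pytest

import lightresponse as lr
from lightresponse.optimizers import (
    Bounds,
    DEConfig,
    GAConfig,
    LMConfig,
    OptResult,
    SAConfig,
    de_minimize,
    ga_minimize,
    lm_fit,
    sa_minimize,
)

SPHERE_BOUNDS = Bounds(np.full(3, -5.0), np.full(3, 5.0))


def sphere(x):
    return float(np.dot(x, x))


class TestDifferentialEvolution:
    def test_sphere_minimum(self):
        res = de_minimize(sphere, SPHERE_BOUNDS, DEConfig(seed=1))
        assert res.converged
        assert res.best_objective < 1e-6
        np.testing.assert_allclose(res.best_params, 0.0, atol=1e-3)

    def test_recovers_rectangular_parameters_within_one_percent(self, clean_rect_dataset):
        ds, truth = clean_rect_dataset
        m = lr.get_model("rectangular")
        res = de_minimize(lr.rss_objective(m, ds), Bounds.from_model(m), DEConfig(seed=7))
        rel = np.abs(res.best_params - np.array(truth)) / np.array(truth)
        assert np.all(rel < 0.01)

    def test_fixed_seed_is_bit_reproducible(self, noisy_rect_dataset):
        ds, _ = noisy_rect_dataset
        m = lr.get_model("rectangular")
        cfg = DEConfig(seed=3, max_iterations=40)
        a = de_minimize(lr.rss_objective(m, ds), Bounds.from_model(m), cfg)
        b = de_minimize(lr.rss_objective(m, ds), Bounds.from_model(m), cfg)
        assert a.best_objective == b.best_objective
        np.testing.assert_array_equal(a.best_params, b.best_params)
        np.testing.assert_array_equal(a.trajectory, b.trajectory)

    @pytest.mark.parametrize("repair", ["reflect", "clip", "resample"])
    def test_every_evaluated_candidate_stays_in_bounds(self, repair):
        bounds = Bounds(np.array([-1.0, 0.0]), np.array([1.0, 2.0]))
        seen = []

        def recording(x):
            seen.append(x.copy())
            return sphere(x)

        de_minimize(recording, bounds, DEConfig(seed=2, max_iterations=30, bound_repair=repair))
        seen = np.array(seen)
        assert np.all(seen >= bounds.lower - 1e-12)
        assert np.all(seen <= bounds.upper + 1e-12)

    def test_best_objective_trajectory_is_monotone(self, noisy_rect_dataset):
        ds, _ = noisy_rect_dataset
        m = lr.get_model("rectangular")
        res = de_minimize(lr.rss_objective(m, ds), Bounds.from_model(m),
                          DEConfig(seed=9, max_iterations=120))
        assert np.all(np.diff(res.trajectory) <= 0.0)
        assert len(res.trajectory) == 120

    def test_matches_exhaustive_grid_search_on_two_parameter_reduction(self, noisy_rect_dataset):
        # fix Rd at truth, search (a, Amax) only; the oracle is a brute-force
        # 500x500 scan of the same box written out in plain numpy
        ds, truth = noisy_rect_dataset
        rd = truth[2]
        obs = ds.a_net
        I = ds.irradiance

        def objective(x):
            a, amax = x
            denom = a * I + amax
            if np.any(denom <= 0):
                return math.inf
            return float(np.sum((obs - (a * I * amax / denom - rd)) ** 2))

        a_grid = np.linspace(1e-4, 1.0, 500)
        amax_grid = np.linspace(1e-2, 100.0, 500)
        A, M = np.meshgrid(a_grid, amax_grid, indexing="ij")
        pred = (A[..., None] * I * M[..., None]) / (A[..., None] * I + M[..., None])
        rss_grid = np.sum((obs - (pred - rd)) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmin(rss_grid), rss_grid.shape)

        res = de_minimize(objective, Bounds(np.array([1e-4, 1e-2]), np.array([1.0, 100.0])),
                          DEConfig(seed=4))
        assert res.best_objective <= rss_grid[i, j] + 1e-12
        # the grid argmin localizes the continuous optimum only to ~one cell
        # (it may sit in a neighbouring cell along a curved valley)
        assert abs(res.best_params[0] - a_grid[i]) <= 1.5 * (a_grid[1] - a_grid[0])
        assert abs(res.best_params[1] - amax_grid[j]) <= 1.5 * (amax_grid[1] - amax_grid[0])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DEConfig(population_size=3)
        with pytest.raises(ValueError):
            DEConfig(F=0.0)
        with pytest.raises(ValueError):
            DEConfig(CR=1.5)
        with pytest.raises(ValueError):
            DEConfig(bound_repair="wrap")

    def test_infeasible_objective_reports_nonfinite(self):
        res = de_minimize(lambda x: math.inf, SPHERE_BOUNDS, DEConfig(seed=1, max_iterations=5))
        assert not res.converged
        assert res.failure_reason == "nonfinite_objective"


class TestLevenbergMarquardt:
    def test_converges_immediately_at_the_optimum(self, clean_rect_dataset):
        ds, truth = clean_rect_dataset
        res = lm_fit(lr.get_model("rectangular"), ds, truth)
        assert res.converged
        assert res.best_objective == pytest.approx(0.0, abs=1e-20)
        assert len(res.trajectory) <= 2

    def test_polishes_a_coarse_de_solution(self, noisy_rect_dataset):
        ds, _ = noisy_rect_dataset
        m = lr.get_model("rectangular")
        de_res = de_minimize(lr.rss_objective(m, ds), Bounds.from_model(m),
                             DEConfig(seed=5, max_iterations=30))
        lm_res = lm_fit(m, ds, de_res.best_params)
        assert lm_res.converged
        assert lm_res.best_objective <= de_res.best_objective

    def test_accepted_steps_strictly_decrease_rss(self, noisy_rect_dataset):
        ds, _ = noisy_rect_dataset
        res = lm_fit(lr.get_model("rectangular"), ds, np.array([0.4, 60.0, 30.0]))
        assert np.all(np.diff(res.trajectory) < 0.0)

    def test_invalid_start_fails_immediately(self, noisy_rect_dataset):
        ds, _ = noisy_rect_dataset
        res = lm_fit(lr.get_model("nonrectangular"), ds, np.array([2.0, 0.05, 20.0, 1.0]))
        assert not res.converged
        assert res.failure_reason == "nonfinite_objective"

    def test_random_box_starts_sometimes_fail_on_nonrectangular(self, noisy_suite):
        # the hallmark initial-value sensitivity: some uniform draws from the
        # search box do not converge
        ds = noisy_suite[2].dataset  # a nonrectangular-generated curve
        sweep = lr.initial_value_sweep(ds, "nonrectangular", n_trials=40, seed=3)
        assert sweep.n_failed > 0
        assert sweep.n_failed < sweep.n_trials  # and some succeed

    def test_agrees_with_scipy_least_squares_from_a_good_start(self, noisy_rect_dataset):
        scipy_opt = pytest.importorskip("scipy.optimize")
        ds, truth = noisy_rect_dataset
        m = lr.get_model("rectangular")
        start = np.array([0.03, 15.0, 0.5])
        ours = lm_fit(m, ds, start)

        def resid(p):
            return ds.a_net - m.predict(p, ds.irradiance)

        ref = scipy_opt.least_squares(resid, start, method="lm")
        assert ours.converged
        assert ours.best_objective == pytest.approx(2.0 * ref.cost, rel=1e-6)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LMConfig(ftol=0.0)
        with pytest.raises(ValueError):
            LMConfig(jacobian="analytic")

    def test_central_difference_jacobian_also_converges(self, noisy_rect_dataset):
        ds, _ = noisy_rect_dataset
        res = lm_fit(lr.get_model("rectangular"), ds, np.array([0.03, 15.0, 0.5]),
                     LMConfig(jacobian="central_difference"))
        assert res.converged


class TestBaselines:
    def test_ga_sphere(self):
        res = ga_minimize(sphere, SPHERE_BOUNDS, GAConfig(seed=1))
        assert res.best_objective < 1e-2

    def test_sa_sphere(self):
        res = sa_minimize(sphere, SPHERE_BOUNDS, SAConfig(seed=1))
        assert res.best_objective < 1e-2

    @pytest.mark.parametrize("minimize,config", [
        (ga_minimize, GAConfig(seed=6, max_iterations=60)),
        (sa_minimize, SAConfig(seed=6, max_iterations=60)),
    ])
    def test_baselines_are_seed_reproducible(self, minimize, config):
        a = minimize(sphere, SPHERE_BOUNDS, config)
        b = minimize(sphere, SPHERE_BOUNDS, config)
        assert a.best_objective == b.best_objective
        np.testing.assert_array_equal(a.best_params, b.best_params)

    def test_sa_fits_clean_rectangular_curve_well(self, clean_rect_dataset):
        ds, _ = clean_rect_dataset
        m = lr.get_model("rectangular")
        res = sa_minimize(lr.rss_objective(m, ds), Bounds.from_model(m), SAConfig(seed=2))
        assert lr.r_squared(m, res.best_params, ds) >= 0.99


class TestContracts:
    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            Bounds(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            Bounds(np.array([0.0]), np.array([np.inf]))

    def test_failed_result_requires_a_reason(self):
        with pytest.raises(ValueError):
            OptResult(best_params=np.zeros(2), best_objective=1.0,
                      converged=False, failure_reason="none")
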