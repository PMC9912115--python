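"""Moving-horizon estimator tests: exact fixed points, parameter recovery
against the virtual-plant oracle, median robustness, bound feasibility."""

import dataclasses

import numpy as np
import pytest

from presscontrol import (
    MovingHorizonEstimator,
    VirtualPlant,
    default_estimator_config,
    get_parameters,
    make_scenario,
    median_disturbance,
    mhe_update,
)


def _window(scenario, n=31):
    plant = VirtualPlant(scenario)
    return [plant.step(t, scenario.u0)[0] for t in range(n)]


def _cs1_scenario(plant_params, seed=0, noise_scale=0.0):
    sc = make_scenario("cs1_no_pmm", seed=seed, horizon_end=40,
                       noise_scale=noise_scale)
    return dataclasses.replace(sc, plant_params=plant_params)


NOMINAL_THETA = {"rho_b": 0.365, "rho_c": 0.265, "kaw_a": 0.80}


class TestMedianDisturbance:
    def test_zero_residuals(self):
        assert np.all(median_disturbance(np.zeros((5, 4))) == 0.0)

    def test_constant_residual(self):
        assert median_disturbance([3.0, 3.0, 3.0]) == 3.0

    def test_robust_to_outlier(self):
        # unlike the mean (34.33), the median ignores the gross error
        assert median_disturbance([1.0, 2.0, 100.0]) == 2.0

    def test_even_length_midpoint(self):
        assert median_disturbance([1.0, 2.0, 3.0, 10.0]) == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_disturbance([])


class TestFixedPoints:
    def test_zero_mismatch_returns_incumbent_exactly(self, geometry):
        sc = make_scenario("cs1_no_pmm", noise_scale=0.0, horizon_end=40)
        window = _window(sc)
        b = mhe_update(window, NOMINAL_THETA, sc.model_params, geometry,
                       default_estimator_config("case1"))
        assert b.theta_hat == NOMINAL_THETA
        assert all(z == 0.0 for z in b.zeta.values())
        assert b.objective_value == 0.0

    def test_returned_objective_never_worse_than_incumbent(self, geometry):
        sc = _cs1_scenario(get_parameters("mild_pmm"), noise_scale=1.0)
        window = _window(sc)
        cfg = default_estimator_config("case1")
        est = MovingHorizonEstimator(window, sc.model_params, geometry, cfg)
        incumbent = est.evaluate(NOMINAL_THETA).objective_value
        fitted = est.fit(NOMINAL_THETA)
        assert fitted.objective_value <= incumbent

    def test_estimates_respect_bounds(self, geometry):
        # plant bulk density outside a narrowed admissible box: the
        # estimate must stop at the bound, never cross it
        sc = _cs1_scenario(get_parameters("no_pmm").replace(rho_b=0.43))
        cfg = default_estimator_config("case1")
        bounds = dict(cfg.theta_bounds)
        bounds["rho_b"] = (0.33, 0.40)
        cfg = dataclasses.replace(cfg, theta_bounds=bounds)
        b = mhe_update(_window(sc), NOMINAL_THETA, sc.model_params, geometry, cfg)
        assert 0.33 <= b.theta_hat["rho_b"] <= 0.40
        assert b.theta_hat["rho_b"] == pytest.approx(0.40, rel=1e-6)


class TestParameterRecovery:
    @pytest.mark.parametrize("pname,true_val", [
        ("rho_b", 0.390), ("rho_c", 0.290), ("kaw_a", 0.77)])
    def test_noise_free_single_parameter_recovery(self, geometry, pname, true_val):
        plant_p = get_parameters("no_pmm").replace(**{pname: true_val})
        sc = _cs1_scenario(plant_p)
        b = mhe_update(_window(sc), NOMINAL_THETA, sc.model_params, geometry,
                       default_estimator_config("case1"))
        assert abs(b.theta_hat[pname] - true_val) / true_val < 1e-3

    def test_noise_free_silica_recovery(self, geometry):
        sc = make_scenario("cs2_silica_steps", noise_scale=0.0, horizon_end=40)
        sc = dataclasses.replace(
            sc, disturbance_schedule=((0, "glidant_conc_cl", 0.35),))
        b = mhe_update(_window(sc), {"glidant_conc_cl": 0.2}, sc.model_params,
                       geometry, default_estimator_config("case2"),
                       glidant_active=True)
        assert abs(b.theta_hat["glidant_conc_cl"] - 0.35) / 0.35 < 1e-3

    def test_noisy_bulk_density_recovery_median_over_replicates(self, geometry):
        # 50 seeded replicates of the mild-mismatch window with default
        # sensor noise: the median estimate stays within 2% of truth
        estimates = []
        for seed in range(50):
            sc = _cs1_scenario(get_parameters("mild_pmm"), seed=seed,
                               noise_scale=1.0)
            b = mhe_update(_window(sc), NOMINAL_THETA, sc.model_params,
                           geometry, default_estimator_config("case1"))
            estimates.append(b.theta_hat["rho_b"])
        assert abs(np.median(estimates) - 0.390) / 0.390 < 0.02

    def test_high_pmm_reduces_residual_without_exact_recovery(self, geometry):
        # six mismatched parameters, three estimated: recovery is not
        # guaranteed, but the fit must still reduce the window residual
        sc = _cs1_scenario(get_parameters("high_pmm"))
        cfg = default_estimator_config("case1")
        est = MovingHorizonEstimator(_window(sc), sc.model_params, geometry, cfg)
        before = est.evaluate(NOMINAL_THETA).objective_value
        after = est.fit(NOMINAL_THETA).objective_value
        assert after < 0.5 * before


class TestWindowHandling:
    def test_short_startup_window_accepted(self, geometry):
        sc = _cs1_scenario(get_parameters("mild_pmm"))
        b = mhe_update(_window(sc, n=5), NOMINAL_THETA, sc.model_params,
                       geometry, default_estimator_config("case1"))
        assert b.converged

    def test_window_truncated_to_n_past_plus_one(self, geometry):
        sc = _cs1_scenario(get_parameters("mild_pmm"))
        cfg = default_estimator_config("case1")
        est = MovingHorizonEstimator(_window(sc, n=40), sc.model_params,
                                     geometry, cfg)
        assert len(est.window) == cfg.n_past + 1

    def test_empty_window_rejected(self, geometry):
        sc = make_scenario("cs1_no_pmm")
        with pytest.raises(ValueError):
            MovingHorizonEstimator([], sc.model_params, geometry,
                                   default_estimator_config("case1"))
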