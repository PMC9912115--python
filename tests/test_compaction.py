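"""Unit tests for the compaction model: hand-evaluated examples of every
equation, analytic limits, monotonicity and purity properties."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from presscontrol import (
    CompactionModelError,
    ModelParameters,
    ModelValidityError,
    ProcessInputs,
    ToolingGeometry,
    evaluate_outputs,
    evaluate_outputs_soft,
    get_parameters,
)
from presscontrol.compaction import (
    bulk_density_from_factor,
    compression_volume,
    elastic_recovery,
    fill_volume,
    glidant_bulk_density,
    glidant_shear,
    kawakita_force,
    lumped_rho_factor,
    lumped_sigma_factor,
    production_rate,
    relative_density,
    tablet_weight,
    tensile_critical_density,
    tensile_strength,
)


@pytest.fixture
def geom():
    return ToolingGeometry()


@pytest.fixture
def p1():
    return get_parameters("no_pmm")


@pytest.fixture
def p2():
    return get_parameters("cs2_nominal")


class TestDieVolumes:
    def test_cylinder_only_when_cup_vanishes(self):
        g = ToolingGeometry(cup_depth_h=1e-9)
        assert fill_volume(g, 8.0) == pytest.approx(200 * math.pi, rel=1e-6)

    def test_fill_volume_hand_value(self, geom):
        # cylinder 628.32 + one cup pi*76/6
        assert fill_volume(geom, 8.0) == pytest.approx(
            628.3185 + math.pi * 76 / 6, abs=1e-3)

    def test_compression_volume_has_two_cups(self, geom):
        cup_fill = fill_volume(geom, 5.0) - math.pi * 25 * 5.0
        cup_comp = compression_volume(geom, 5.0) - math.pi * 25 * 5.0
        assert cup_comp == pytest.approx(2 * cup_fill)

    def test_nonpositive_depth_rejected(self, geom):
        with pytest.raises(CompactionModelError):
            fill_volume(geom, 0.0)
        with pytest.raises(CompactionModelError):
            compression_volume(geom, -1.0)


class TestWeightAndRate:
    def test_weight_correction_factor_unity(self, geom, p1):
        u = ProcessInputs(8.0, 4.0, 1.2, geom.feed_frame_speed_nF)
        p0 = p1.replace(xi1=0.0, xi2=0.0)
        w = tablet_weight(p0, geom, u, 0.365)
        assert w == pytest.approx(0.365 * fill_volume(geom, 8.0))

    def test_weight_hand_value(self, geom, p1):
        # rho_b = 0.365, V = 668.11 mm^3, nT/nF = 1, Hfill/D = 0.8
        u = ProcessInputs(8.0, 4.0, 1.2, geom.feed_frame_speed_nF)
        assert tablet_weight(p1, geom, u, 0.365) == pytest.approx(240.94, abs=0.01)

    def test_weight_linear_in_bulk_density(self, geom, p1):
        u = ProcessInputs(8.0, 4.0, 1.2, 50.0)
        assert tablet_weight(p1, geom, u, 0.8) == pytest.approx(
            2 * tablet_weight(p1, geom, u, 0.4))

    def test_production_rate_hand_value(self):
        assert production_rate(210.0, 54.76, 10) == pytest.approx(6.9, rel=1e-3)

    def test_rate_linear_in_each_argument(self):
        base = production_rate(200.0, 50.0, 10)
        assert production_rate(400.0, 50.0, 10) == pytest.approx(2 * base)
        assert production_rate(200.0, 100.0, 10) == pytest.approx(2 * base)
        assert production_rate(200.0, 50.0, 20) == pytest.approx(2 * base)


class TestDensitiesAndForces:
    def test_relative_density_full(self):
        assert relative_density(100.0, 100.0, 1.0) == 1.0

    def test_relative_density_hand_value(self, geom):
        v = compression_volume(geom, 4.0)
        assert relative_density(240.94, v, 1.53) == pytest.approx(0.400, abs=5e-4)

    def test_relative_density_halved_volume(self):
        assert relative_density(50.0, 50.0, 1.53) == pytest.approx(
            2 * relative_density(50.0, 100.0, 1.53))

    def test_kawakita_zero_at_critical_density(self, p1):
        assert kawakita_force(p1.rho_c, p1, 10.0) == 0.0

    def test_kawakita_hand_value(self, p1):
        # 78.54 mm^2 * 10.26 MPa * (0.265/0.159) = 1.343 kN
        assert kawakita_force(0.53, p1, 10.0) == pytest.approx(1.343, abs=1e-3)

    def test_kawakita_invalid_above_denominator_zero(self, p1):
        limit = p1.rho_c / (1 - p1.kaw_a)
        with pytest.raises(ModelValidityError):
            kawakita_force(limit + 1e-9, p1, 10.0)

    @given(st.floats(min_value=0.27, max_value=1.3))
    def test_kawakita_strictly_increasing(self, rho):
        p = get_parameters("no_pmm")
        f1 = kawakita_force(rho, p, 10.0)
        f2 = kawakita_force(rho + 1e-4, p, 10.0)
        assert f2 > f1


class TestElasticRecoveryAndTensile:
    def test_recovery_at_full_compaction_is_eps0(self, p1):
        assert elastic_recovery(1.0, p1) == pytest.approx(p1.eps0)

    def test_recovery_zero_at_critical(self, p1):
        assert elastic_recovery(p1.rho_c_eps, p1) == 0.0
        assert elastic_recovery(p1.rho_c_eps - 0.1, p1) == 0.0  # clamped

    def test_recovery_hand_value(self, p1):
        assert elastic_recovery(0.785, p1) == pytest.approx(0.04, abs=1e-12)

    def test_tensile_at_zero_porosity_is_sigma0(self, p1):
        assert tensile_strength(1.0, 0.0, 18.0, p1) == pytest.approx(11.67)

    def test_tensile_zero_at_critical_density(self, p1):
        assert tensile_strength(p1.rho_c0, 0.0, 18.0, p1) == 0.0

    def test_tensile_hand_value(self, p1):
        expect = 11.67 * (1 - 0.5 * math.exp(0.215))
        assert tensile_strength(0.785, 0.0, 18.0, p1) == pytest.approx(expect)

    def test_tensile_increasing_in_density_on_grid(self, p1):
        # grid starts at the glidant-shifted critical density
        rho_crit = tensile_critical_density(
            lumped_sigma_factor(0.2, 18.7, p1), p1)
        grid = np.linspace(rho_crit + 1e-9, 1.0, 1000)
        vals = [tensile_strength(r, 0.2, 18.7, p1) for r in grid]
        assert np.all(np.diff(vals) > 0)

    def test_glidant_lowers_strength_ceiling(self, p1):
        assert tensile_strength(0.9, 0.5, 18.7, p1) < tensile_strength(
            0.9, 0.0, 18.7, p1)

    def test_critical_density_bounds(self, p1):
        assert tensile_critical_density(0.0, p1) == pytest.approx(p1.rho_c0)
        assert tensile_critical_density(1e12, p1) == pytest.approx(p1.rho_cinf, abs=1e-9)


class TestGlidantModels:
    def test_mixing_time_baseline_without_holdup(self):
        g = ToolingGeometry(holdup_mfh=1e-12)
        assert glidant_shear(g, 6.9) == pytest.approx(g.gamma0)

    def test_mixing_time_hand_value(self):
        g = ToolingGeometry()  # 1 kg holdup
        assert glidant_shear(g, 6.9) == pytest.approx(10 + 60 / 6.9)

    def test_mixing_time_decreasing_in_rate(self):
        g = ToolingGeometry()
        assert glidant_shear(g, 8.0) < glidant_shear(g, 6.9)

    def test_zero_rate_rejected(self):
        with pytest.raises(CompactionModelError):
            glidant_shear(ToolingGeometry(), 0.0)

    def test_bulk_density_asymptotes(self, p2):
        assert bulk_density_from_factor(0.0, p2) == pytest.approx(0.330)
        assert bulk_density_from_factor(1e9, p2) == pytest.approx(0.450, abs=1e-6)
        assert bulk_density_from_factor(1.0, p2) == pytest.approx(0.390)

    @given(st.floats(min_value=0.0, max_value=1e6))
    def test_bulk_density_bounded_and_increasing(self, c):
        p = get_parameters("cs2_nominal")
        v = bulk_density_from_factor(c, p)
        assert p.rho_b_0 <= v <= p.rho_b_inf
        assert bulk_density_from_factor(c + 1.0, p) > v

    def test_lumped_factors_vanish_at_zero_concentration(self, p2):
        assert lumped_sigma_factor(0.0, 18.7, p2) == 0.0
        assert lumped_rho_factor(0.0, 18.7, 10.0, p2) == 0.0

    def test_negative_concentration_rejected(self, p2):
        with pytest.raises(CompactionModelError):
            glidant_bulk_density(-0.1, 18.7, p2, 10.0)


class TestCompositeMap:
    def test_nominal_calibration_reproduces_setpoints(self, geom, p1):
        from presscontrol import calibrate_nominal_inputs
        u0 = calibrate_nominal_inputs(p1, geom)
        out = evaluate_outputs(u0, p1, geom)
        assert out.tablet_weight_W == pytest.approx(210.0, rel=5e-3)
        assert out.precompression_force_Fpc == pytest.approx(0.3, rel=5e-3)
        assert out.production_rate == pytest.approx(6.9, rel=5e-3)
        assert out.tensile_strength_sigmat == pytest.approx(4.2, rel=5e-3)

    def test_composition_matches_chained_hand_values(self, geom, p1):
        # xi1 = xi2 = 0 and glidant inactive: the composite equals the
        # per-equation chain evaluated by hand
        p0 = p1.replace(xi1=0.0, xi2=0.0)
        u = ProcessInputs(8.0, 4.0, 1.2, geom.feed_frame_speed_nF, 0.0)
        out = evaluate_outputs(u, p0, geom)
        W = 0.365 * fill_volume(geom, 8.0)
        assert out.tablet_weight_W == pytest.approx(W)
        assert out.production_rate == pytest.approx(
            production_rate(W, geom.feed_frame_speed_nF, 10))
        rho_pc = relative_density(W, compression_volume(geom, 4.0), 1.53)
        assert out.precompression_force_Fpc == pytest.approx(
            kawakita_force(rho_pc, p0, 10.0))
        rho_id = relative_density(W, compression_volume(geom, 1.2), 1.53)
        rho_tab = (1 - elastic_recovery(rho_id, p0)) * rho_id
        gamma = glidant_shear(geom, out.production_rate)
        assert out.tensile_strength_sigmat == pytest.approx(
            tensile_strength(rho_tab, 0.0, gamma, p0))

    def test_evaluation_is_pure(self, geom, p2):
        u = ProcessInputs(6.0, 4.0, 1.1, 55.0, 0.25)
        a = evaluate_outputs(u, p2, geom, glidant_active=True)
        b = evaluate_outputs(u, p2, geom, glidant_active=True)
        assert a == b

    def test_output_invariants(self, geom, p1):
        u = ProcessInputs(7.0, 4.2, 1.1, 50.0, 0.2)
        out = evaluate_outputs(u, p1, geom)
        assert 0 < out.tablet_relative_density < 1
        assert out.tablet_relative_density <= out.in_die_relative_density
        assert min(out.tablet_weight_W, out.precompression_force_Fpc,
                   out.main_compression_force_Fpunch, out.production_rate,
                   out.tensile_strength_sigmat) >= 0

    def test_soft_mode_penalises_instead_of_raising(self, geom, p1):
        # main compression thickness so small that the in-die density
        # leaves the Kawakita validity interval
        u = ProcessInputs(16.0, 8.0, 1.0, 20.0, 0.2)
        with pytest.raises(ModelValidityError):
            evaluate_outputs(u, p1, geom)
        out, pen = evaluate_outputs_soft(u, p1, geom)
        assert pen > 0
        assert np.isfinite(out.main_compression_force_Fpunch)

    def test_glidant_fixed_point_consistency(self, geom, p2):
        # the reported mixing time must satisfy its own defining relation
        u = ProcessInputs(6.0, 4.0, 1.1, 55.0, 0.3)
        out = evaluate_outputs(u, p2, geom, glidant_active=True)
        assert out.mixing_time_gamma == pytest.approx(
            glidant_shear(geom, out.production_rate), abs=1e-9)
        assert out.bulk_density == pytest.approx(
            glidant_bulk_density(0.3, out.mixing_time_gamma, p2, geom.gamma0))


class TestParameterValidation:
    def test_invariants_enforced(self):
        with pytest.raises(CompactionModelError):
            ModelParameters(rho_c=1.5)
        with pytest.raises(CompactionModelError):
            ModelParameters(rho_c0=0.7, rho_cinf=0.6)
        with pytest.raises(CompactionModelError):
            ModelParameters(rho_b_inf=0.3, rho_b_0=0.4, r1=1, r2=1, r3=1)

    def test_input_ordering_enforced(self):
        with pytest.raises(CompactionModelError):
            ProcessInputs(4.0, 5.0, 1.0, 50.0)
        with pytest.raises(CompactionModelError):
            ProcessInputs(8.0, 4.0, 4.5, 50.0)

    def test_parameter_yaml_roundtrip(self, tmp_path):
        from presscontrol import dump_parameters, load_parameters
        p = get_parameters("cs2_nominal")
        dump_parameters(p, tmp_path / "p.yaml")
        assert load_parameters(tmp_path / "p.yaml") == p

    def test_packaged_fixtures_match_builtin_sets(self):
        from presscontrol.params import (PARAMETER_SETS, load_parameters,
                                         packaged_parameter_path)
        for name, p in PARAMETER_SETS.items():
            assert load_parameters(packaged_parameter_path(name)) == p
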