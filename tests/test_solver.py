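import numpy as np
import pytest

from icas_hemoflow import (
    FluidProperties,
    NumericsConfig,
    OutletModel,
    StenosisSpec,
    VesselGeometry,
    channel_poiseuille_reference,
    inlet_condition,
    jet_reynolds,
    make_stenosis_profile,
    mean_arterial_pressure,
    poiseuille_reference,
    solve_steady_flow,
    wall_profile,
)
from icas_hemoflow.errors import (
    ConvergenceError,
    InputError,
    RegimeError,
    UnconvergedFieldError,
)

MU = 3.5e-3


class TestInletCondition:
    def test_mean_velocity_formula(self):
        inlet = inlet_condition(0.9, 0.3, 0.002, 130, 80)
        assert inlet.mean_velocity == pytest.approx(0.5)

    def test_flow_rate_is_velocity_times_area(self):
        inlet = inlet_condition(0.4, 0.4, 0.002, 130, 80)
        assert inlet.flow_rate == pytest.approx(0.4 * np.pi * 0.002 ** 2)
        assert inlet.flow_rate == pytest.approx(5.027e-6, rel=1e-3)

    def test_equal_velocities_collapse_to_that_velocity(self):
        inlet = inlet_condition(0.6, 0.6, 0.001, 120, 70)
        assert inlet.mean_velocity == pytest.approx(0.6)

    def test_map_conversion(self):
        # MAP = 80 + (130-80)/3 mmHg, converted at 133.322 Pa/mmHg
        assert mean_arterial_pressure(130, 80) == pytest.approx(
            (80 + 50 / 3) * 133.322)

    @pytest.mark.parametrize("psv, edv, r, s, d", [
        (0.3, 0.5, 0.002, 130, 80),     # edv > psv
        (0.5, 0.0, 0.002, 130, 80),     # edv zero
        (0.5, 0.3, 0.0, 130, 80),       # zero radius
        (0.5, 0.3, 0.002, 80, 80),      # systolic == diastolic
    ])
    def test_invalid_inputs_rejected(self, psv, edv, r, s, d):
        with pytest.raises(InputError):
            inlet_condition(psv, edv, r, s, d)


class TestPoiseuilleReference:
    def test_hand_evaluated_case(self):
        dp, tau = poiseuille_reference(5.027e-6, 0.002, 0.01, MU)
        assert dp == pytest.approx(28.0, rel=2e-3)
        assert tau == pytest.approx(2.80, rel=2e-3)

    def test_radius_scaling_laws(self):
        dp1, tau1 = poiseuille_reference(5e-6, 0.002, 0.01, MU)
        dp2, tau2 = poiseuille_reference(5e-6, 0.004, 0.01, MU)
        assert dp2 == pytest.approx(dp1 / 16.0)
        assert tau2 == pytest.approx(tau1 / 8.0)

    def test_zero_flow(self):
        assert poiseuille_reference(0.0, 0.002, 0.01, MU) == (0.0, 0.0)

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            poiseuille_reference(1e-6, -0.002, 0.01, MU)


class TestStraightTube:
    def test_matches_poiseuille(self, straight_tube, reference_inlet,
                                coarse_numerics):
        f = solve_steady_flow(straight_tube, reference_inlet,
                              numerics=coarse_numerics)
        prof = wall_profile(f)
        dp_ref, tau_ref = poiseuille_reference(
            reference_inlet.flow_rate, 0.002, 0.02, MU)
        dp = prof.wall_pressure[0] - prof.wall_pressure[-1]
        assert dp == pytest.approx(dp_ref, rel=0.02)
        mid = slice(24, 72)
        assert prof.wss[mid] == pytest.approx(tau_ref, rel=0.02)

    def test_pressure_anchored_at_inlet_map(self, straight_tube,
                                            reference_inlet, coarse_numerics):
        f = solve_steady_flow(straight_tube, reference_inlet,
                              numerics=coarse_numerics)
        assert f.pressure[0].mean() == pytest.approx(
            reference_inlet.mean_arterial_pressure, rel=1e-9)

    def test_mass_conserved(self, straight_tube, reference_inlet,
                            coarse_numerics):
        f = solve_steady_flow(straight_tube, reference_inlet,
                              numerics=coarse_numerics)
        assert f.mass_conservation_error <= 0.005

    def test_null_flow_is_hydrostatic(self, straight_tube, coarse_numerics):
        from icas_hemoflow.solver.conditions import InletCondition
        inlet = InletCondition(psv=0.0, edv=0.0, mean_velocity=0.0,
                               flow_rate=0.0,
                               mean_arterial_pressure=12000.0,
                               inlet_radius=0.002)
        f = solve_steady_flow(straight_tube, inlet, numerics=coarse_numerics)
        assert np.all(f.u_axial == 0)
        assert np.allclose(f.pressure, 12000.0)
        prof = wall_profile(f)
        assert np.all(prof.wss == 0)


class TestStenosedFlow:
    def test_drop_exceeds_poiseuille(self, stenosed_case_50):
        geom, inlet, field, prof = stenosed_case_50
        dp_ref, tau_ref = poiseuille_reference(
            inlet.flow_rate, 1.5e-3, geom.total_length, MU)
        dp = prof.wall_pressure[0] - prof.wall_pressure[-1]
        assert dp > dp_ref
        assert prof.wss.max() > tau_ref

    def test_terminal_pressure_below_origin(self, stenosed_case_50):
        _, _, _, prof = stenosed_case_50
        assert prof.wall_pressure[-1] < prof.wall_pressure[0]

    def test_arc_length_strictly_increasing_and_spans_vessel(
            self, stenosed_case_50):
        geom, _, _, prof = stenosed_case_50
        assert np.all(np.diff(prof.arc_length) > 0)
        assert prof.arc_length[0] == 0.0
        assert prof.arc_length[-1] >= geom.total_length

    def test_mass_conserved(self, stenosed_case_50):
        _, _, field, _ = stenosed_case_50
        assert field.mass_conservation_error <= 0.005

    def test_reynolds_cap_refuses_fast_jets(self, coarse_numerics):
        R = 1.5e-3
        spec = StenosisSpec(R, 85.0, 8e-3, 6 * 2 * R + 4e-3)
        geom = make_stenosis_profile(spec, 8e-3 + 36 * 2 * R, 1025)
        inlet = inlet_condition(0.9, 0.45, R, 130, 80)
        assert jet_reynolds(geom, inlet, FluidProperties()) > 2000
        with pytest.raises(RegimeError):
            solve_steady_flow(geom, inlet, numerics=coarse_numerics)

    def test_nonconvergence_reports_residual(self, stenosed_case_50):
        geom, inlet, _, _ = stenosed_case_50
        bad = NumericsConfig(axial_cells=96, radial_cells=24,
                             max_iterations=1, picard_warmup=1,
                             convergence_tolerance=1e-14)
        with pytest.raises(ConvergenceError) as err:
            solve_steady_flow(geom, inlet, numerics=bad)
        assert err.value.final_residual is not None
        assert err.value.final_residual > 1e-14

    def test_unconverged_field_refused_by_profiler(self, stenosed_case_50):
        _, _, field, _ = stenosed_case_50
        import copy
        broken = copy.copy(field)
        broken.converged = False
        with pytest.raises(UnconvergedFieldError):
            wall_profile(broken)


class TestOutletModels:
    def test_resistance_outlet_anchors_downstream(self, straight_tube,
                                                  reference_inlet,
                                                  coarse_numerics):
        outlet = OutletModel(kind="resistance", distal_pressure=9000.0,
                             distal_resistance=1e9)
        f = solve_steady_flow(straight_tube, reference_inlet, outlet,
                              numerics=coarse_numerics)
        target = 9000.0 + 1e9 * reference_inlet.flow_rate
        assert f.pressure[-1].mean() == pytest.approx(target, rel=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(InputError):
            OutletModel(kind="windkessel")


class TestPlanarMode:
    def test_channel_matches_plane_poiseuille(self):
        R = 1.5e-3
        z = np.linspace(0.0, 0.04, 513)
        walls = np.column_stack([np.full_like(z, R), np.full_like(z, R)])
        geom = VesselGeometry(z, walls, "planar", R)
        inlet = inlet_condition(0.4, 0.4, R, 130, 80)
        f = solve_steady_flow(geom, inlet, numerics=NumericsConfig(
            axial_cells=128, radial_cells=32))
        q = inlet.mean_velocity * 2 * R
        dp_ref, tau_ref = channel_poiseuille_reference(q, 2 * R, 0.04, MU)
        for side in ("upper", "lower"):
            prof = wall_profile(f, side=side)
            dp = prof.wall_pressure[0] - prof.wall_pressure[-1]
            assert dp == pytest.approx(dp_ref, rel=0.02)
            assert prof.wss[32:96] == pytest.approx(tau_ref, rel=0.02)

    def test_eccentric_lesion_loads_plaque_wall(self):
        R = 1.5e-3
        spec = StenosisSpec(R, 50.0, 8e-3, 6 * 2 * R + 4e-3, side="upper")
        geom = make_stenosis_profile(spec, 8e-3 + 36 * 2 * R, 2049)
        inlet = inlet_condition(0.4, 0.16, R, 130, 80)
        f = solve_steady_flow(geom, inlet, numerics=NumericsConfig(
            axial_cells=128, radial_cells=32))
        up = wall_profile(f, side="upper")
        lo = wall_profile(f, side="lower")
        assert up.side_label == "upper"
        assert up.wss.max() > lo.wss.max()


class TestNumericsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"axial_cells": 8},
        {"convergence_tolerance": 0.0},
        {"under_relaxation": 1.5},
        {"central_weight": -0.1},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InputError):
            NumericsConfig(**kwargs)
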