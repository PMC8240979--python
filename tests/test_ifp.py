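"""Steady pressure solve: oracle agreement, bounds, budgets, velocity."""

import dataclasses

import numpy as np
import pytest

from perisim.geometry import build_mesh
from perisim.ifp import (PressureField, analytic_sphere_ifp, fluid_budget,
                         solve_ifp, starling_source, velocity_from_pressure)
from perisim.params import BASELINE_TISSUE, effective_pressure, preset
from perisim.verification import TOLERANCES, run_convergence

P_SS = effective_pressure(BASELINE_TISSUE)


class TestStarlingSource:
    def test_necrotic_region_has_no_source(self):
        assert starling_source(500.0, BASELINE_TISSUE, 1) == 0.0

    def test_source_vanishes_at_effective_pressure(self):
        assert starling_source(P_SS, BASELINE_TISSUE, 0) == pytest.approx(0.0)

    def test_zero_pressure_filtration_rate(self):
        # L_p * S/V * P_ss = 2.1e-11 * 2.0e4 * 1530.6
        assert starling_source(0.0, BASELINE_TISSUE, 0) == pytest.approx(
            6.4285e-4, rel=1e-3)


class TestAnalyticSphere:
    def test_boundary_value_zero(self):
        assert analytic_sphere_ifp(0.01, 0.005, BASELINE_TISSUE, 0.01) \
            == pytest.approx(0.0, abs=1e-8 * P_SS)

    def test_no_core_closed_form_center(self):
        t = BASELINE_TISSUE
        alpha = np.sqrt(t.L_p * t.S_over_V / t.K)
        R = 0.01
        expect = P_SS * (1 - alpha * R / np.sinh(alpha * R))
        assert analytic_sphere_ifp(R, 0.0, t, 0.0) == pytest.approx(expect)

    def test_monotone_decreasing(self):
        r = np.linspace(0, 0.01, 200)
        P = analytic_sphere_ifp(0.01, 0.005, BASELINE_TISSUE, r)
        assert np.all(np.diff(P) <= 1e-9 * P_SS)

    def test_radius_outside_domain_raises(self):
        with pytest.raises(ValueError):
            analytic_sphere_ifp(0.01, 0.005, BASELINE_TISSUE, 0.02)


class TestSolve:
    @pytest.mark.parametrize("label,r_n", [("SS", 0.0), ("LS", 0.005)])
    def test_matches_oracle(self, label, r_n):
        _, _, spec = preset(label)
        if r_n == 0.0:
            spec = dataclasses.replace(spec, r_ln=0.0, r_sn=0.0,
                                       has_necrotic_core=False)
        mesh = build_mesh(spec)
        press = solve_ifp(mesh, BASELINE_TISSUE)
        r = np.linspace(0, spec.r_l, 20)
        num = np.interp(r, mesh.nodes, press.P)
        ora = analytic_sphere_ifp(spec.r_l, r_n, BASELINE_TISSUE, r)
        err = np.max(np.abs(num - ora)) / ora.max()
        assert err < TOLERANCES["pressure_oracle_rel"]

    def test_negligible_vascular_leak_gives_flat_field(self):
        t = dataclasses.replace(BASELINE_TISSUE, L_p=1e-30)
        _, _, spec = preset("SS")
        mesh = build_mesh(spec)
        press = solve_ifp(mesh, t)
        vel = velocity_from_pressure(press, t)
        assert press.P.max() < 1e-6 * P_SS
        assert vel.IFV_max < 1e-15

    def test_max_pressure_bounded_by_p_ss(self, baseline_cases):
        for case in baseline_cases.values():
            assert case.pressure.P.max() <= P_SS * (1 + 1e-9)
            assert case.pressure.P.min() >= -1e-9 * P_SS

    def test_surface_pressure_is_zero(self, baseline_cases):
        for case in baseline_cases.values():
            bc = case.pressure.P[case.mesh.dirichlet_nodes]
            assert np.allclose(bc, 0.0)

    def test_large_geometry_max_pressure(self, baseline_cases):
        for g in ("LS", "LE", "LT"):
            assert baseline_cases[g].metrics.IFP_max == pytest.approx(
                P_SS, rel=2e-3)

    def test_smaller_nodules_have_lower_peak_pressure(self, baseline_cases):
        for small, large in (("SS", "LS"), ("SE", "LE"), ("ST", "LT")):
            assert baseline_cases[small].metrics.IFP_max \
                <= baseline_cases[large].metrics.IFP_max

    def test_singular_without_dirichlet(self):
        _, _, spec = preset("SS")
        mesh = build_mesh(spec)
        mesh.dirichlet_nodes = np.array([], dtype=int)
        with pytest.raises(ValueError, match="singular"):
            solve_ifp(mesh, BASELINE_TISSUE)


class TestVelocity:
    def test_uniform_pressure_gives_zero_velocity(self):
        _, _, spec = preset("SS")
        mesh = build_mesh(spec)
        press = PressureField(mesh=mesh, P=np.full(mesh.n_nodes, 7.0))
        vel = velocity_from_pressure(press, BASELINE_TISSUE)
        assert vel.IFV_max == pytest.approx(0.0, abs=1e-20)

    def test_linear_ramp_recovers_conductivity(self):
        _, _, spec = preset("SS")
        mesh = build_mesh(spec)
        g = 1.0e5  # Pa/m
        press = PressureField(mesh=mesh, P=g * mesh.nodes)
        vel = velocity_from_pressure(press, BASELINE_TISSUE)
        assert vel.IFV_max == pytest.approx(BASELINE_TISSUE.K * g, rel=1e-9)

    def test_outward_flow_at_surface(self, ls_case):
        # radially outward where pressure decreases outward
        assert ls_case.velocity.u[-1] > 0


class TestBudgetsAndConvergence:
    def test_fluid_balance_closes(self, baseline_cases):
        for case in baseline_cases.values():
            bud = fluid_budget(case.pressure, case.tissue)
            assert bud["closure_rel"] < TOLERANCES["budget_rel"]

    def test_gradient_flux_consistent(self, ls_case):
        bud = fluid_budget(ls_case.pressure, ls_case.tissue)
        assert bud["closure_rel_gradient"] < 5e-2

    def test_pressure_converges_second_order(self):
        _, _, spec = preset("SS")
        spec = dataclasses.replace(spec, r_ln=0.0, r_sn=0.0,
                                   has_necrotic_core=False)
        r_eval = 0.00123  # off-node radius: P1 interpolation error is O(h^2)
        oracle = analytic_sphere_ifp(spec.r_l, 0.0, BASELINE_TISSUE, r_eval)

        def sampled_pressure(h):
            # ratio=1 gives uniform spacing so the whole mesh refines with h
            mesh = build_mesh(spec, target_h=h, ratio=1.0)
            press = solve_ifp(mesh, BASELINE_TISSUE)
            return np.interp(r_eval, mesh.nodes, press.P)

        rep = run_convergence(sampled_pressure, [24e-6, 12e-6, 6e-6],
                              reference=oracle)
        assert 1.7 <= rep.observed_order <= 3.0
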