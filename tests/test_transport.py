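"""Drug transport: sink closures, oracles, maximum principle, budgets."""

import dataclasses
from types import SimpleNamespace

import numpy as np
import pytest

from perisim.geometry import build_mesh
from perisim.ifp import solve_ifp, velocity_from_pressure
from perisim.metrics import extract_profile, apd
from perisim.params import BASELINE_TISSUE, DRUGS, preset
from perisim.transport import (cellular_sink, mass_budget, solve_transport,
                               steady_transport, vascular_peclet,
                               vascular_sink)
from perisim.verification import (TOLERANCES, sphere_diffusion_transient_oracle,
                                  sphere_reaction_diffusion_oracle)

CIS = DRUGS["cisplatin"]


def _quiet_sphere(label="SS"):
    """Small sphere without core and with negligible flow, for 1D oracles."""
    _, _, spec = preset(label)
    spec = dataclasses.replace(spec, r_ln=0.0, r_sn=0.0,
                               has_necrotic_core=False)
    tissue = dataclasses.replace(BASELINE_TISSUE, L_p=1e-30)
    mesh = build_mesh(spec)
    press = solve_ifp(mesh, tissue)
    vel = velocity_from_pressure(press, tissue)
    return spec, tissue, mesh, press, vel


class TestSinkClosures:
    def test_peclet_zero_for_no_filtration(self):
        assert vascular_peclet(0.0, CIS, BASELINE_TISSUE) == 0.0

    def test_peclet_baseline_surface_value(self):
        pe = vascular_peclet(6.43e-4, CIS, BASELINE_TISSUE)
        assert pe == pytest.approx(0.0225, rel=1e-2)

    def test_peclet_inverse_in_wall_permeability(self):
        d2 = dataclasses.replace(CIS, P_c=2 * CIS.P_c)
        assert vascular_peclet(1e-4, d2, BASELINE_TISSUE) == pytest.approx(
            0.5 * vascular_peclet(1e-4, CIS, BASELINE_TISSUE))

    def test_peclet_requires_permeable_wall(self):
        broken = SimpleNamespace(P_c=0.0, sigma=0.0)
        with pytest.raises(ValueError):
            vascular_peclet(1e-4, broken, BASELINE_TISSUE)

    def test_vascular_sink_values(self):
        assert vascular_sink(0.0, 0.0225, CIS, BASELINE_TISSUE, 0) == 0.0
        # Pe_v -> 0 limit: P_c * S/V * C0
        lim = vascular_sink(CIS.C0, 0.0, CIS, BASELINE_TISSUE, 0)
        assert lim == pytest.approx(CIS.P_c * BASELINE_TISSUE.S_over_V * CIS.C0)
        val = vascular_sink(0.8, 0.0225, CIS, BASELINE_TISSUE, 0)
        assert val == pytest.approx(2.26e-2, rel=1e-2)
        assert vascular_sink(0.8, 0.0225, CIS, BASELINE_TISSUE, 1) == 0.0

    def test_cellular_sink_values(self):
        assert cellular_sink(0.0, CIS, 0) == 0.0
        assert cellular_sink(0.8, CIS, 0) == pytest.approx(5.856e-4)
        assert cellular_sink(0.8, CIS, 1) == 0.0


class TestOracles:
    def test_pure_diffusion_matches_series_solution(self):
        spec, tissue, mesh, press, vel = _quiet_sphere()
        drug = dataclasses.replace(CIS, beta=1e-30, P_c=1e-30)
        conc = solve_transport(mesh, vel, press, drug, tissue,
                               t_end=600.0, dt=5.0, store_every=120)
        oracle = sphere_diffusion_transient_oracle(spec.r_l, drug.D, drug.C0)
        expect = oracle(mesh.nodes, 600.0)
        err = np.max(np.abs(conc.final - expect)) / drug.C0
        assert err < TOLERANCES["reaction_diffusion_rel"]

    def test_steady_reaction_diffusion_matches_closed_form(self):
        spec, tissue, mesh, press, vel = _quiet_sphere()
        conc = steady_transport(mesh, vel, press, CIS, tissue)
        k_e = CIS.beta + CIS.P_c * tissue.S_over_V  # Pe_v = 0 with no flow
        oracle = sphere_reaction_diffusion_oracle(spec.r_l, CIS.D, k_e, CIS.C0)
        err = np.max(np.abs(conc.final - oracle(mesh.nodes))) / CIS.C0
        assert err < TOLERANCES["reaction_diffusion_rel"]

    def test_diffusion_dominated_limit_fills_domain(self):
        spec, tissue, mesh, press, vel = _quiet_sphere()
        fast = dataclasses.replace(CIS, D=1e-5)
        conc = steady_transport(mesh, vel, press, fast, tissue)
        assert conc.final.min() > 0.99 * CIS.C0


class TestDiscreteProperties:
    def test_maximum_principle_everywhere(self, baseline_cases):
        for case in baseline_cases.values():
            C = case.conc.C
            assert C.min() >= -1e-9 * CIS.C0
            assert C.max() <= CIS.C0 * (1 + 1e-9)

    def test_boundary_concentration_held(self, ls_case):
        dn = ls_case.mesh.dirichlet_nodes
        assert np.allclose(ls_case.conc.final[dn], CIS.C0)

    def test_concentration_nondecreasing_in_time(self, ss_step_case):
        C = ss_step_case.conc.C
        assert np.all(np.diff(C, axis=0) >= -1e-12 * CIS.C0)

    def test_mass_budget_closes_per_step(self, ss_step_case):
        assert mass_budget(ss_step_case.conc)["max_rel_error"] \
            < TOLERANCES["budget_rel"]

    def test_steady_agrees_with_long_transient(self):
        spec, tissue, mesh, press, vel = _quiet_sphere()
        tr = solve_transport(mesh, vel, press, CIS, tissue,
                             t_end=3600.0, dt=30.0, store_every=120)
        ss = steady_transport(mesh, vel, press, CIS, tissue)
        err = np.max(np.abs(tr.final - ss.final)) / CIS.C0
        assert err < TOLERANCES["steady_vs_transient"]

    def test_interior_stays_below_surface_concentration(self, ls_case):
        interior = np.setdiff1d(np.arange(ls_case.mesh.n_nodes),
                                ls_case.mesh.dirichlet_nodes)
        assert np.all(ls_case.conc.final[interior] < CIS.C0)

    def test_cell_peclet_guard(self):
        _, _, spec = preset("SS")
        mesh = build_mesh(spec)
        press = solve_ifp(mesh, BASELINE_TISSUE)
        vel = velocity_from_pressure(press, BASELINE_TISSUE)
        sticky = dataclasses.replace(CIS, D=1e-15)
        with pytest.raises(RuntimeError, match="Peclet"):
            solve_transport(mesh, vel, press, sticky, BASELINE_TISSUE,
                            t_end=60.0)


class TestSinkDominance:
    def test_vascular_loss_exceeds_cellular_loss(self):
        assert CIS.P_c * BASELINE_TISSUE.S_over_V > CIS.beta

    def test_weaker_vascular_sink_deepens_penetration(self):
        _, _, spec = preset("LS")
        mesh = build_mesh(spec)
        press = solve_ifp(mesh, BASELINE_TISSUE)
        vel = velocity_from_pressure(press, BASELINE_TISSUE)
        from perisim.geometry import axes_of
        ax = axes_of(spec)[0]
        depths = []
        for pc in (CIS.P_c, CIS.P_c * 1e-2):
            drug = dataclasses.replace(CIS, P_c=pc)
            conc = steady_transport(mesh, vel, press, drug, BASELINE_TISSUE)
            depths.append(apd(extract_profile(conc, ax, 801), drug))
        assert depths[1] > depths[0]
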