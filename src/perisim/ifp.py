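"""Steady interstitial-fluid-pressure (IFP) solve and Darcy velocity.

The interstitium is a rigid porous medium: ``u = -K grad(P_i)`` (Darcy), with
steady incompressible continuity ``div(u) = F_v`` where the transvascular
filtration source follows Starling's hypothesis,

    F_v = L_p (S/V) (P_v - P_i - c (pi_v - pi_i))      in viable tissue,
    F_v = 0                                            in the necrotic core,

and lymphatic drainage is absent (solid tumors lack functional lymphatics).
The source is linear in ``P_i``, so the steady problem is a single sparse
linear solve of

    -K lap(P_i) = a (P_ss - P_i),   a = L_p S/V,   P_ss = P_v - c (pi_v - pi_i)

with ``P_i = 0`` on the instillate-bathed outer surface and zero flux on
symmetry facets.  ``P_ss`` bounds the attainable pressure from above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fem
from .geometry import Mesh, VIABLE
from .params import TissueParams, effective_pressure
from .verification import sphere_pressure_oracle

__all__ = [
    "PressureField", "VelocityField",
    "starling_source", "solve_ifp", "velocity_from_pressure",
    "analytic_sphere_ifp", "fluid_budget",
]


@dataclass
class PressureField:
    """Steady IFP solution on a mesh."""

    mesh: Mesh
    P: np.ndarray                 # Pa, nodal
    residuals: list = field(default_factory=list)
    converged: bool = False

    @property
    def max(self) -> float:
        return float(self.P.max())


@dataclass
class VelocityField:
    """Darcy interstitial fluid velocity, elementwise constant."""

    mesh: Mesh
    u: np.ndarray                 # (M,) in 1D, (M, 2) in 2D, m/s
    IFV_max: float = 0.0

    def magnitude(self) -> np.ndarray:
        if self.u.ndim == 1:
            return np.abs(self.u)
        return np.linalg.norm(self.u, axis=1)


def starling_source(P_i, tissue: TissueParams, region) -> np.ndarray:
    """Volumetric transvascular fluid gain ``F_v`` (1/s).

    Zero in the necrotic core; ``L_p (S/V) (P_ss - P_i)`` in viable tissue.
    Accepts scalar or array ``P_i``/``region``.
    """
    P_i = np.asarray(P_i, dtype=float)
    region = np.asarray(region)
    a = tissue.L_p * tissue.S_over_V
    P_ss = effective_pressure(tissue)
    return np.where(region == VIABLE, a * (P_ss - P_i), 0.0)


def solve_ifp(mesh: Mesh, tissue: TissueParams,
              boundary_pressure: float = 0.0) -> PressureField:
    """Solve the steady Darcy/Starling pressure problem.

    Returns a :class:`PressureField` with the algebraic residual history;
    convergence requires a residual drop of at least four orders of magnitude
    (the direct sparse solve reaches machine precision).
    """
    if mesh.dirichlet_nodes.size == 0:
        raise ValueError("no Dirichlet facet: the pressure problem is singular")
    asm = fem.assemble(mesh)
    a_elem = np.where(mesh.region == VIABLE,
                      tissue.L_p * tissue.S_over_V, 0.0)
    P_ss = effective_pressure(tissue)
    A = tissue.K * asm.stiffness + asm.reaction_matrix(a_elem)
    b = np.zeros(mesh.n_nodes)
    tri = mesh.cells
    np.add.at(b, tri.ravel(),
              (a_elem[:, None] * asm.cell_mass * P_ss).ravel())
    vals = np.full(mesh.dirichlet_nodes.size, boundary_pressure)
    A_ff, rhs, free = fem.apply_dirichlet_rows(A, b, mesh.dirichlet_nodes, vals)
    x = fem.solve_sparse(A_ff, rhs)
    P = np.empty(mesh.n_nodes)
    P[free] = x
    P[mesh.dirichlet_nodes] = vals
    r0 = float(np.linalg.norm(rhs)) or 1.0
    rf = float(np.linalg.norm(A_ff @ x - rhs))
    fieldP = PressureField(mesh=mesh, P=P, residuals=[r0, rf],
                           converged=rf <= 1e-4 * r0)
    if not fieldP.converged:
        raise RuntimeError(
            f"pressure solve did not converge: residuals {fieldP.residuals}")
    fieldP.meta = {"assembly": asm, "A": A, "b": b}
    return fieldP


def velocity_from_pressure(pressure: PressureField,
                           tissue: TissueParams) -> VelocityField:
    """Darcy velocity ``u = -K grad(P_i)`` from the P1 pressure gradient."""
    asm = getattr(pressure, "meta", {}).get("assembly") \
        or fem.assemble(pressure.mesh)
    u = -tissue.K * asm.gradient(pressure.P)
    vf = VelocityField(mesh=pressure.mesh, u=u)
    vf.IFV_max = float(vf.magnitude().max())
    return vf


def analytic_sphere_ifp(R: float, r_n: float, tissue: TissueParams, r):
    """Closed-form spherical IFP (verification oracle).

    Piecewise solution of the radial Darcy/Starling problem: constant in the
    zero-source core (zero flux at the interface), a ``sinh``/``cosh``
    combination in the viable shell with ``P(R) = 0``.  Delegates to the
    independent closed form in :mod:`perisim.verification`.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < -1e-15) or np.any(r > R * (1 + 1e-12)):
        raise ValueError("radius outside [0, R]")
    return sphere_pressure_oracle(R, r_n, tissue)(r)


def fluid_budget(pressure: PressureField, tissue: TissueParams) -> dict:
    """Global steady fluid balance check.

    Compares the volume integral of the Starling source against the outward
    Darcy flux through the outer surface, extracted both variationally
    (discretely conservative) and from the boundary-element pressure
    gradient.  Returns absolute values (m^3/s for the full nodule) and the
    relative closure errors.
    """
    mesh = pressure.mesh
    asm = getattr(pressure, "meta", {}).get("assembly") or fem.assemble(mesh)
    a_elem = np.where(mesh.region == VIABLE,
                      tissue.L_p * tissue.S_over_V, 0.0)
    P_ss = effective_pressure(tissue)
    P_elem = pressure.P[mesh.cells].mean(axis=1)
    fv = a_elem * (P_ss - P_elem)
    source = asm.integrate_elem(fv) * mesh.volume_multiplier

    meta = getattr(pressure, "meta", {})
    if "A" in meta:
        A, b = meta["A"], meta["b"]
    else:  # rebuild the unconstrained system
        A = tissue.K * asm.stiffness + asm.reaction_matrix(a_elem)
        b = np.zeros(mesh.n_nodes)
        np.add.at(b, mesh.cells.ravel(),
                  (a_elem[:, None] * asm.cell_mass * P_ss).ravel())
    res_flux = -fem.boundary_residual_flux(A, pressure.P, b,
                                           mesh.dirichlet_nodes)
    res_flux *= mesh.volume_multiplier

    grad_flux = _gradient_surface_flux(pressure, tissue, asm)
    rel = abs(res_flux - source) / max(abs(source), 1e-300)
    rel_grad = abs(grad_flux - source) / max(abs(source), 1e-300)
    return {
        "source_m3_s": source,
        "surface_flux_m3_s": res_flux,
        "surface_flux_gradient_m3_s": grad_flux,
        "closure_rel": rel,
        "closure_rel_gradient": rel_grad,
    }


def _gradient_surface_flux(pressure: PressureField, tissue: TissueParams,
                           asm: fem.Assembly) -> float:
    """Outward Darcy flux from boundary-element gradients (direct check)."""
    mesh = pressure.mesh
    u = -tissue.K * asm.gradient(pressure.P)
    if mesh.mode == "radial_1d":
        R = mesh.nodes[-1]
        return float(u[-1]) * R * R * mesh.volume_multiplier
    flux = 0.0
    # map each outer facet to the triangle that owns it
    tri = mesh.cells
    edge_owner = {}
    for t_idx in range(tri.shape[0]):
        a, b, c = tri[t_idx]
        for e in ((a, b), (b, c), (c, a)):
            edge_owner[frozenset(e)] = t_idx
    xy = mesh.nodes
    from .geometry import OUTER_SURFACE
    for (n0, n1, marker) in mesh.facets:
        if marker != OUTER_SURFACE or n0 == n1:
            continue
        t_idx = edge_owner.get(frozenset((n0, n1)))
        if t_idx is None:
            continue
        p0, p1 = xy[n0], xy[n1]
        edge = p1 - p0
        nrm = np.array([edge[1], -edge[0]])
        # orient outward: away from the owning triangle's centroid
        cen = xy[tri[t_idx]].mean(axis=0)
        if np.dot(nrm, 0.5 * (p0 + p1) - cen) < 0:
            nrm = -nrm
        rho_mid = 0.5 * (p0[0] + p1[0])
        flux += float(np.dot(u[t_idx], nrm)) * rho_mid
    return flux * mesh.volume_multiplier
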