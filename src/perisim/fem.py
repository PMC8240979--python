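"""P1 finite-element assembly on radial and axisymmetric meshes.

The weak forms carry the symmetry weight of the reduced domain: ``r^2`` for
the spherical-radial mode and the cylindrical radius ``rho`` for the
axisymmetric mode (the constant angular factor, 4*pi or 2*pi times the mirror
count, is ``Mesh.volume_multiplier`` and is applied only when absolute
volumes or fluxes are reported).

Mass and reaction terms are lumped (row-summed), which together with the
boundary-layer-resolving meshes keeps the transport operator essentially
monotone; advection uses the non-conservative form ``u . grad(C)`` with an
elementwise-constant velocity taken from the P1 pressure gradient.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "Assembly", "assemble", "apply_dirichlet_rows", "boundary_residual_flux",
]


class Assembly:
    """Per-element geometric quantities of one mesh.

    Attributes
    ----------
    mass : (N,) lumped mass vector, weighted element measure per node.
    stiffness : sparse (N, N) matrix of ``int grad(phi_a).grad(phi_b) w``.
    cell_mass : (M, k) contribution of each element to its nodes' lumped mass
        (k = 2 in 1D, 3 in 2D), used for per-element reaction coefficients.
    grads : element shape-function gradients.
    measure : (M,) weighted element measure (for volume integrals).
    """

    def __init__(self, mesh):
        self.mesh = mesh
        if mesh.mode == "radial_1d":
            self._init_1d(mesh)
        else:
            self._init_2d(mesh)

    # -- 1D spherical-radial ------------------------------------------------
    def _init_1d(self, mesh):
        r = mesh.nodes
        e = mesh.cells
        r0 = r[e[:, 0]]
        r1 = r[e[:, 1]]
        h = r1 - r0
        # int_e r^2 dr
        m2 = h * (r0 * r0 + r0 * r1 + r1 * r1) / 3.0
        # int_e phi_a r^2 dr
        phi0 = h * (r0 * r0 / 4.0 + r0 * r1 / 6.0 + r1 * r1 / 12.0)
        phi1 = h * (r0 * r0 / 12.0 + r0 * r1 / 6.0 + r1 * r1 / 4.0)
        self.cell_mass = np.column_stack([phi0, phi1])
        self.measure = m2
        n = r.size
        self.mass = np.zeros(n)
        np.add.at(self.mass, e[:, 0], phi0)
        np.add.at(self.mass, e[:, 1], phi1)
        k = m2 / (h * h)
        rows = np.concatenate([e[:, 0], e[:, 0], e[:, 1], e[:, 1]])
        cols = np.concatenate([e[:, 0], e[:, 1], e[:, 0], e[:, 1]])
        vals = np.concatenate([k, -k, -k, k])
        self.stiffness = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        self.grads = np.column_stack([-1.0 / h, 1.0 / h])  # (M, 2)
        self.h_elem = h

    # -- 2D axisymmetric ----------------------------------------------------
    def _init_2d(self, mesh):
        xy = mesh.nodes
        tri = mesh.cells
        p0 = xy[tri[:, 0]]
        p1 = xy[tri[:, 1]]
        p2 = xy[tri[:, 2]]
        d1 = p1 - p0
        d2 = p2 - p0
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        area = 0.5 * np.abs(det)
        # grad(phi_a), shape (M, 3, 2)
        g = np.empty((tri.shape[0], 3, 2))
        g[:, 0, 0] = p1[:, 1] - p2[:, 1]
        g[:, 0, 1] = p2[:, 0] - p1[:, 0]
        g[:, 1, 0] = p2[:, 1] - p0[:, 1]
        g[:, 1, 1] = p0[:, 0] - p2[:, 0]
        g[:, 2, 0] = p0[:, 1] - p1[:, 1]
        g[:, 2, 1] = p1[:, 0] - p0[:, 0]
        g /= det[:, None, None]
        self.grads = g
        rho = xy[:, 0]
        rho_tri = rho[tri]                       # (M, 3)
        rho_bar = rho_tri.mean(axis=1)
        self.measure = area * rho_bar            # int_T rho dA (exact, rho linear)
        # lumped mass: int_T phi_a rho dA = area*(2 rho_a + rho_b + rho_c)/12
        cm = (area[:, None] * (rho_tri + 3.0 * rho_bar[:, None])) / 12.0
        self.cell_mass = cm
        n = xy.shape[0]
        self.mass = np.zeros(n)
        np.add.at(self.mass, tri.ravel(), cm.ravel())
        # stiffness with rho weight
        w = self.measure
        ga = g[:, :, None, :]
        gb = g[:, None, :, :]
        k_loc = (ga * gb).sum(axis=-1) * w[:, None, None]   # (M, 3, 3)
        rows = np.repeat(tri, 3, axis=1).ravel()
        cols = np.tile(tri, (1, 3)).ravel()
        self.stiffness = sp.csr_matrix(
            (k_loc.ravel(), (rows, cols)), shape=(n, n))

    # -- generic operators --------------------------------------------------
    def reaction_matrix(self, coeff_elem: np.ndarray) -> sp.csr_matrix:
        """Lumped reaction operator for an elementwise coefficient (1/s)."""
        tri = self.mesh.cells
        n = self.mesh.n_nodes
        vals = (coeff_elem[:, None] * self.cell_mass).ravel()
        idx = tri.ravel()
        diag = np.zeros(n)
        np.add.at(diag, idx, vals)
        return sp.diags(diag).tocsr()

    def advection_matrix(self, u_elem: np.ndarray) -> sp.csr_matrix:
        """Operator for ``u . grad(C)`` with elementwise-constant velocity,
        tested against lumped node weights."""
        tri = self.mesh.cells
        n = self.mesh.n_nodes
        if self.mesh.mode == "radial_1d":
            udg = u_elem[:, None] * self.grads            # (M, 2)
        else:
            udg = (u_elem[:, None, :] * self.grads).sum(-1)  # (M, 3)
        k = tri.shape[1]
        rows = np.repeat(tri, k, axis=1).ravel()
        cols = np.tile(tri, (1, k)).ravel()
        vals = (self.cell_mass[:, :, None] * udg[:, None, :]).ravel()
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def gradient(self, field: np.ndarray) -> np.ndarray:
        """Elementwise P1 gradient: (M,) in 1D, (M, 2) in 2D."""
        tri = self.mesh.cells
        if self.mesh.mode == "radial_1d":
            return (field[tri] * self.grads).sum(axis=1)
        return (field[tri][:, :, None] * self.grads).sum(axis=1)

    def integrate_elem(self, coeff_elem: np.ndarray) -> float:
        """Weighted integral of an elementwise-constant field over the
        reduced domain (multiply by ``volume_multiplier`` for the nodule)."""
        return float(np.dot(coeff_elem, self.measure))


def assemble(mesh) -> Assembly:
    return Assembly(mesh)


def apply_dirichlet_rows(A: sp.csr_matrix, b: np.ndarray,
                         idx: np.ndarray, values: np.ndarray):
    """Return the reduced system on free nodes plus bookkeeping.

    ``A_ff x_f = b_f - A_fd x_d``; returns ``(A_ff (csc), rhs, free_idx)``.
    """
    n = A.shape[0]
    mask = np.ones(n, dtype=bool)
    mask[idx] = False
    free = np.where(mask)[0]
    A_ff = A[free][:, free].tocsc()
    rhs = b[free] - A[free][:, idx] @ values
    return A_ff, rhs, free


def boundary_residual_flux(A: sp.csr_matrix, x: np.ndarray, b: np.ndarray,
                           idx: np.ndarray) -> float:
    """Variational outward-flux extraction at the Dirichlet nodes.

    For the unconstrained assembly ``A, b``, the residual restricted to the
    constrained rows equals the weak boundary flux carried by those nodes;
    this is the superconvergent (discretely conservative) flux.
    """
    r = A @ x - b
    return float(r[idx].sum())


def solve_sparse(A_csc, rhs: np.ndarray) -> np.ndarray:
    return spla.spsolve(A_csc, rhs)
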