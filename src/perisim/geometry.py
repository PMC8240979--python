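"""Nodule geometries, region classification and interface-fitted meshes.

Spheres are discretized in 1D spherical-radial mode; ellipsoids and cropped
(dome-shaped) nodules in 2D axisymmetric mode about their symmetry axis.
Meshes are interface-fitted: the necrotic/viable interface coincides with
element boundaries, so region properties are never smeared across it, and the
radial spacing is graded so the thin pressure and concentration boundary
layers under the nodule surface are resolved.

Coordinate conventions
----------------------
* Sphere: radial coordinate ``r`` in [0, R].
* Ellipsoid (LE/SE): axisymmetric about the long axis.  Mesh coordinates are
  ``(rho, z)`` with ``z`` along the long axis; the quarter domain
  ``z >= 0`` is meshed and the ``z = 0`` plane is a symmetry plane.
* Cropped (LT/ST): the ellipsoid is cut through its center by a plane
  parallel to the long axis, leaving a dome of depth ``r_s`` below the flat
  face.  The dome is axisymmetric about the depth axis; mesh coordinates are
  ``(rho, z)`` with ``z <= 0`` pointing into the tissue and the flat face at
  ``z = 0``.  By default the flat face (the contact area with the peritoneal
  wall) is a zero-flux plane, not part of the instillate-bathed surface; a
  switch makes it an outer Dirichlet surface instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .params import GeometrySpec

__all__ = [
    "VIABLE", "NECROTIC", "Axis", "Mesh",
    "region_of", "axes_of", "build_mesh",
]

VIABLE = 0
NECROTIC = 1

#: boundary facet markers
OUTER_SURFACE = "outer_surface"
SYMMETRY_AXIS = "symmetry_axis"
SYMMETRY_PLANE = "symmetry_plane"


@dataclass(frozen=True)
class Axis:
    """A profile axis from the nodule center to the outer surface."""

    name: str              # "LA" or "SA"
    half_length: float     # m, center to surface along the axis


@dataclass
class Mesh:
    """Discretization of one nodule.

    ``nodes`` is ``(N,)`` radii in 1D mode or ``(N, 2)`` ``(rho, z)``
    coordinates in axisymmetric mode.  ``cells`` is ``(M, 2)`` segments or
    ``(M, 3)`` triangles.  ``region`` tags each cell VIABLE or NECROTIC.
    ``axis_lines`` maps an axis name to ``(node_indices, distances)`` along
    that axis, sorted center -> surface.  ``volume_multiplier`` converts the
    reduced-domain weighted measure to the full nodule volume (4*pi for the
    radial mode, 2*pi times the mirror count for axisymmetric mode).
    """

    mode: str
    nodes: np.ndarray
    cells: np.ndarray
    region: np.ndarray
    dirichlet_nodes: np.ndarray
    facets: List[Tuple[int, int, str]]
    axis_lines: Dict[str, Tuple[np.ndarray, np.ndarray]]
    volume_multiplier: float
    h: float
    spec: GeometrySpec
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

def _scaled_radius2(point: np.ndarray, spec: GeometrySpec,
                    a: float, b: float) -> float:
    """Squared elliptic norm of ``point`` w.r.t. half-lengths (a, b)."""
    p = np.asarray(point, dtype=float).ravel()
    if spec.shape == "sphere":
        r2 = float(p @ p)
        return r2 / (a * a)
    if spec.shape == "ellipsoid":
        # long axis is the first coordinate for 2/3-vectors (x, transverse...)
        long2 = p[0] ** 2
        perp2 = float(p[1:] @ p[1:])
        return long2 / (a * a) + perp2 / (b * b)
    # cropped: last coordinate is depth (z <= 0), the rest in-plane
    depth2 = p[-1] ** 2
    plane2 = float(p[:-1] @ p[:-1])
    return plane2 / (a * a) + depth2 / (b * b)


def region_of(point, spec: GeometrySpec) -> int:
    """Classify a point as VIABLE or NECROTIC.

    ``point`` may be a scalar radius (spheres), a 2-vector or a 3-vector.
    For ellipsoids the first coordinate lies along the long axis; for cropped
    shapes the last coordinate is the (non-positive) depth below the flat
    face.  Raises ``ValueError`` for points outside the nodule.
    """
    p = np.atleast_1d(np.asarray(point, dtype=float))
    if spec.shape == "cropped" and p[-1] > 1e-12 * spec.r_s:
        raise ValueError("point lies above the flat face of the cropped nodule")
    outer = _scaled_radius2(p, spec, spec.r_l, spec.r_s)
    if outer > 1.0 + 1e-9:
        raise ValueError("point lies outside the nodule")
    if not spec.has_necrotic_core or spec.r_ln == 0.0:
        return VIABLE
    inner = _scaled_radius2(p, spec, spec.r_ln, spec.r_sn)
    return NECROTIC if inner <= 1.0 else VIABLE


def axes_of(spec: GeometrySpec) -> List[Axis]:
    """Profile axes: one radius for spheres, LA and SA otherwise."""
    if spec.shape == "sphere":
        return [Axis("LA", spec.r_l)]
    return [Axis("LA", spec.r_l), Axis("SA", spec.r_s)]


# ---------------------------------------------------------------------------
# 1D radial mesh (spheres)
# ---------------------------------------------------------------------------

def _graded_from(end: float, start: float, h_fine: float,
                 ratio: float, h_cap: float) -> np.ndarray:
    """Nodes from ``start`` to ``end`` with spacing ``h_fine`` at ``end``,
    growing geometrically toward ``start`` (returned ascending)."""
    pts = [end]
    h = h_fine
    while pts[-1] - h > start + 0.25 * h:
        pts.append(pts[-1] - h)
        h = min(h * ratio, h_cap)
    pts.append(start)
    return np.array(pts[::-1])


def _build_radial(spec: GeometrySpec, h_surf: float, ratio: float,
                  h_cap_frac: float) -> Mesh:
    R = spec.r_l
    r_n = spec.r_ln
    h_cap = R * h_cap_frac
    if r_n > 0.0:
        shell = _graded_from(R, r_n, h_surf, ratio, h_cap)
        # grade gently away from the interface into the core as well
        core = _graded_from(r_n, 0.0, min(4 * h_surf, h_cap), ratio, h_cap)
        nodes = np.concatenate([core[:-1], shell])
    else:
        nodes = _graded_from(R, 0.0, h_surf, ratio, h_cap)
    cells = np.column_stack([np.arange(nodes.size - 1),
                             np.arange(1, nodes.size)])
    mid = 0.5 * (nodes[cells[:, 0]] + nodes[cells[:, 1]])
    if spec.has_necrotic_core and r_n > 0.0:
        region = np.where(mid < r_n, NECROTIC, VIABLE).astype(np.uint8)
    else:
        region = np.full(cells.shape[0], VIABLE, dtype=np.uint8)
    axis_idx = np.arange(nodes.size)
    mesh = Mesh(
        mode="radial_1d",
        nodes=nodes,
        cells=cells,
        region=region,
        dirichlet_nodes=np.array([nodes.size - 1]),
        facets=[(nodes.size - 1, nodes.size - 1, OUTER_SURFACE)],
        axis_lines={"LA": (axis_idx, nodes.copy())},
        volume_multiplier=4.0 * np.pi,
        h=h_surf,
        spec=spec,
    )
    return mesh


# ---------------------------------------------------------------------------
# 2D axisymmetric mesh (ellipsoid / cropped)
# ---------------------------------------------------------------------------

def _elliptic_radius(theta: np.ndarray, a_axis: float, b_perp: float):
    """Distance from center to the ellipse surface along ray ``theta``
    measured from the rotation axis."""
    return 1.0 / np.sqrt((np.cos(theta) / a_axis) ** 2
                         + (np.sin(theta) / b_perp) ** 2)


def _s_levels(s_c: float, ds_min: float, ratio: float, ds_cap: float,
              n_inner: int) -> np.ndarray:
    """Radial parameter levels in [0, 1]: ``n_inner`` uniform levels in the
    core band [0, s_c], then a band graded from ``ds_cap`` down to ``ds_min``
    at the outer surface s = 1."""
    outer = [1.0]
    d = ds_min
    while outer[-1] - d > s_c + 0.25 * d:
        outer.append(outer[-1] - d)
        d = min(d * ratio, ds_cap)
    outer.append(s_c)
    outer = np.array(outer[::-1])
    # rescale so the band ends exactly at s_c without distorting fine spacing
    inner = np.linspace(0.0, s_c, n_inner + 1)
    return np.concatenate([inner[:-1], outer])


def _build_axisymmetric(spec: GeometrySpec, h_surf: float, ratio: float,
                        n_theta: int, n_inner: int,
                        flat_face_dirichlet: bool) -> Mesh:
    cropped = spec.shape == "cropped"
    if cropped:
        # rotation axis = depth axis; theta=0 along -z, theta=pi/2 in-plane
        a_axis, b_perp = spec.r_s, spec.r_l
        a_core, b_core = spec.r_sn, spec.r_ln
        axis_theta0, axis_theta1 = "SA", "LA"
        z_sign = -1.0
    else:
        # rotation axis = long axis; quarter domain z >= 0
        a_axis, b_perp = spec.r_l, spec.r_s
        a_core, b_core = spec.r_ln, spec.r_sn
        axis_theta0, axis_theta1 = "LA", "SA"
        z_sign = 1.0

    theta = np.linspace(0.0, 0.5 * np.pi, n_theta + 1)
    R_out = _elliptic_radius(theta, a_axis, b_perp)
    has_core = spec.r_ln > 0.0
    if has_core:
        R_in = _elliptic_radius(theta, a_core, b_core)
    else:
        R_in = np.zeros_like(R_out)

    s_c = 0.5
    # finest physical spacing at the thickest shell section
    shell_max = float(np.max(R_out - R_in)) if has_core else float(np.max(R_out))
    ds_min = h_surf / shell_max
    ds_cap = max(4.0 * ds_min, 0.035)
    s = _s_levels(s_c, ds_min, ratio, ds_cap, n_inner)
    n_s = s.size  # includes s=0 level

    # physical radius of level (i, j): blended two-band map so that the
    # necrotic interface is exactly the s = s_c level
    S, TH = np.meshgrid(s, theta, indexing="ij")
    Rin_g = np.broadcast_to(R_in, TH.shape)
    Rout_g = np.broadcast_to(R_out, TH.shape)
    if has_core:
        rad = np.where(
            S <= s_c,
            (S / s_c) * Rin_g,
            Rin_g + (S - s_c) / (1.0 - s_c) * (Rout_g - Rin_g),
        )
    else:
        rad = S * Rout_g

    rho = rad * np.sin(TH)
    z = z_sign * rad * np.cos(TH)

    # collapse the degenerate s=0 ring into a single center node (index 0)
    n_cols = n_theta + 1

    def nid(i: int, j) -> np.ndarray:
        """node index of level i (>=1), column j"""
        return 1 + (i - 1) * n_cols + np.asarray(j)

    coords = [np.array([[0.0, 0.0]])]
    coords.append(np.column_stack([rho[1:].ravel(), z[1:].ravel()]))
    nodes = np.vstack(coords)

    tris = []
    regions = []

    def cell_region(i: int) -> int:
        if spec.has_necrotic_core and has_core:
            smid = 0.5 * (s[i] + s[i + 1])
            return NECROTIC if smid < s_c else VIABLE
        return VIABLE

    j = np.arange(n_theta)
    # fan around the center
    fan = np.column_stack([np.zeros(n_theta, dtype=int), nid(1, j), nid(1, j + 1)])
    tris.append(fan)
    regions.append(np.full(n_theta, cell_region(0), dtype=np.uint8))
    # structured quads split into two triangles
    for i in range(1, n_s - 1):
        a = nid(i, j)
        b = nid(i + 1, j)
        c = nid(i + 1, j + 1)
        d = nid(i, j + 1)
        tris.append(np.column_stack([a, b, c]))
        tris.append(np.column_stack([a, c, d]))
        regions.append(np.full(2 * n_theta, cell_region(i), dtype=np.uint8))
    cells = np.vstack(tris)
    region = np.concatenate(regions)

    # boundary bookkeeping
    outer_nodes = nid(n_s - 1, np.arange(n_cols))
    facets: List[Tuple[int, int, str]] = []
    for jj in range(n_theta):
        facets.append((int(outer_nodes[jj]), int(outer_nodes[jj + 1]),
                       OUTER_SURFACE))
    # column node indices along theta = 0 and theta = pi/2
    col_t0 = np.concatenate([[0], [int(nid(i, 0)) for i in range(1, n_s)]])
    col_t1 = np.concatenate([[0], [int(nid(i, n_theta)) for i in range(1, n_s)]])
    for i in range(len(col_t0) - 1):
        facets.append((int(col_t0[i]), int(col_t0[i + 1]), SYMMETRY_AXIS))
    plane_marker = OUTER_SURFACE if (cropped and flat_face_dirichlet) \
        else SYMMETRY_PLANE
    for i in range(len(col_t1) - 1):
        facets.append((int(col_t1[i]), int(col_t1[i + 1]), plane_marker))

    dirichlet = set(int(n) for n in outer_nodes)
    if cropped and flat_face_dirichlet:
        dirichlet.update(int(n) for n in col_t1)
    dirichlet_nodes = np.array(sorted(dirichlet))

    dist_t0 = np.concatenate([[0.0], rad[1:, 0]])
    dist_t1 = np.concatenate([[0.0], rad[1:, n_theta]])
    axis_lines = {
        axis_theta0: (np.asarray(col_t0), dist_t0),
        axis_theta1: (np.asarray(col_t1), dist_t1),
    }

    mesh = Mesh(
        mode="axisymmetric_2d",
        nodes=nodes,
        cells=cells,
        region=region,
        dirichlet_nodes=dirichlet_nodes,
        facets=facets,
        axis_lines=axis_lines,
        volume_multiplier=2.0 * np.pi * (1.0 if cropped else 2.0),
        h=h_surf,
        spec=spec,
        meta={"n_theta": n_theta, "s_levels": s,
              "flat_face_dirichlet": bool(flat_face_dirichlet)},
    )
    return mesh


# ---------------------------------------------------------------------------
# Entry point
# ---------------------------------------------------------------------------

def build_mesh(spec: GeometrySpec, target_h: float | None = None, *,
               ratio: float = 1.12, n_theta: int = 96, n_inner: int = 24,
               flat_face_dirichlet: bool = False,
               force_mode: str | None = None) -> Mesh:
    """Build an interface-fitted mesh for ``spec``.

    ``target_h`` is the radial spacing at the outer surface (m); the interior
    is graded coarser by ``ratio`` per layer.  Defaults resolve the
    drug-concentration boundary layer (tens of micrometers under baseline
    parameters).  Spheres produce a 1D radial mesh unless
    ``force_mode="axisymmetric_2d"`` is given (used for cross-backend
    verification).
    """
    if target_h is None:
        target_h = 3e-6 if spec.shape == "sphere" else 8e-6
    if spec.r_ln > 0.0:
        limit = min(spec.r_sn, spec.r_s - spec.r_sn) / 4.0
    else:
        limit = spec.r_s / 10.0
    if target_h >= limit:
        raise ValueError(
            f"target_h={target_h:g} m too coarse to resolve both zones; "
            f"use target_h < {limit:g} m"
        )
    if spec.shape == "sphere" and force_mode != "axisymmetric_2d":
        return _build_radial(spec, target_h, ratio, h_cap_frac=1 / 30)
    return _build_axisymmetric(spec, target_h, ratio, n_theta, n_inner,
                               flat_face_dirichlet)
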