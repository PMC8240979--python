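# Methods

## Model and assumptions

A single vascularized tumor nodule is bathed in a cytotoxic solution of
fixed concentration.  The model is the classical porous-medium description
of tumor interstitium:

* **Flow.** Rigid tissue, incompressible interstitial fluid, Darcy's law
  `u = -K ∇P_i` with spatially uniform conductivity `K = k/μ`.  The only
  fluid source is Starling filtration from a spatially distributed
  vasculature, `F_v = L_p (S/V)(P_v − P_i − c(π_v − π_i))`; lymphatic
  drainage is absent (solid tumors lack functional lymphatics).  The source
  is linear in `P_i`, so the steady pressure problem is one sparse linear
  solve.  Its zero, `P_ss = P_v − c(π_v − π_i)` = 1530.6 Pa at the tumor
  baseline, is a rigorous upper bound for the IFP with a zero-pressure
  surface; published peak values that exceed it slightly (1533.88 Pa)
  reflect rounding of the tabulated parameters, not attainable pressures.
* **Transport.** Convection–diffusion–reaction for the interstitial
  concentration with the divergence form expanded as
  `∇·(uC) = u·∇C + C F_v` (the flow is not solenoidal).  Losses: first-order
  cellular uptake `βC` and transvascular resorption
  `P_c (S/V) C · Pe_v/(e^{Pe_v}−1)` under the assumption that the vascular
  concentration stays negligible over the 1 h therapeutic window.  The
  factor `Pe_v/(e^{Pe_v}−1)` is evaluated by its series limit for
  `|Pe_v| < 1e-6`.
* **Necrotic core.** No viable cells and no functional vasculature: the
  filtration source and both sinks vanish there; the diffusivity is
  unchanged and all fields are continuous across the interface.  Omitting
  the core (for the robustness study) means activating source and sinks in
  that region, on the identical mesh.
* **Segregation.** Transport never feeds back on flow; the velocity field
  is frozen before the transport solve.

### Geometries

Six parametric nodules: spheres of radius 10/2 mm with cores of half that
radius; prolate ellipsoids with half-axes 20/10 mm (cores 10/5 mm) and the
one-fifth scale versions; and "peritoneal" nodules built by cropping the
ellipsoid through its center with a plane parallel to the long axis,
leaving a dome of in-plane half-length 20 mm and depth 10 mm (core
8.7/4.53 mm; one-fifth scale for the small version).  The cropped core is
constructed as the similarly shaped dome with its flat face in the same
plane; the published description fixes only the two core extents, so the
exact placement inside the dome is a modeling choice (see Limitations).

The flat face is treated as the attachment area to the peritoneal wall: a
zero-flux plane for both pressure and concentration, *not* part of the
instillate-bathed surface.  This is the reading consistent with the
published per-axis penetration metrics — with drug applied on the flat face
the whole long-axis profile would sit at `C0` and its PD% would be 100 —
and with the physical picture of a nodule growing on the wall.  A
configuration switch (`flat_face_dirichlet`) applies the boundary condition
there instead.

## Parameters

All values are stored in SI; printed units (e.g. `P_c` in cm/s) are
converted once at the parsing boundary.  Baseline tissue: `K = 3.1e-14`
m²/(Pa·s) (`k = 3.1e-17` m², `μ = 1e-3` Pa·s), `L_p = 2.1e-11` m/(Pa·s),
`S/V = 2e4` 1/m, `P_v = 2080` Pa, `π_v = 2670` Pa, `π_i = 2000` Pa,
`c = 0.82`.  Drugs: cisplatin `D = 2.5e-10` m²/s, IC50 `6.2e-3` mol/m³;
paclitaxel `D = 0.77e-10` m²/s, IC50 `1.4e-6` mol/m³; shared `β = 7.32e-4`
1/s, `σ = 8.17e-5`, `P_c = 1.43e-6` m/s, `C0 = 0.8` mol/m³ (0.14 mol/m³
for the clinical paclitaxel dose).  Vascular normalization interpolates
(`L_p`, `S/V`, `c`) linearly toward the normal-tissue endpoints
(`2.7e-12`, `7e3`, `0.91`); the tabulated 50% value `L_p = 1.19e-11` is the
rounded midpoint `1.185e-11`, and the computed interpolation is used.  The
permeability sweep takes `k ∈ {6.4e-18, 3.1e-17, 6.4e-17}` m² with `K`
recomputed as `k/μ`.  Fluid density and molecular weight are stored for
provenance but unused (incompressible flow; `D` given directly).

## Discretization

* **Meshes.** Interface-fitted so the necrotic boundary coincides with
  element edges.  Spheres: 1D spherical-radial P1 elements (weight `r²`),
  graded geometrically from 3 µm at the surface (growth 1.12, capped at
  R/30), with a node exactly at the core radius.  Ellipsoids and domes: 2D
  axisymmetric P1 triangles (weight `ρ`) on a structured polar map blended
  so the `s = 0.5` level is exactly the core surface; radial spacing graded
  to 8 µm (at the widest shell section) under the outer surface, 96 angular
  columns, a collapsed center node.  The grading resolves both boundary
  layers: pressure `1/α = sqrt(K/(L_p S/V)) ≈ 0.27` mm and concentration
  `sqrt(D/k_loss) ≈ 50–90` µm.
* **Quadrature/lumping.** Mass and reaction terms are lumped; advection
  uses the elementwise-constant P1 pressure gradient (`u = -K ∇P_i`)
  tested against lumped node weights.  Cell Péclet numbers are ~1e-2 at
  the defaults, so no upwinding or artificial diffusion is used, and a
  guard raises if `Pe_cell > 2`.
* **Time stepping.** Backward Euler with `dt = 30` s to `t = 3600` s
  (the upper end of the clinical 30–60 min exposure; with baseline loss
  rates the profile is quasi-steady well before that, and the steady solve
  is computed alongside — baseline APDs agree to ~1e-3 mm).  The scheme is
  unconditionally stable and, with lumping, discretely conservative: the
  per-step mass balance closes to machine precision, as does the steady
  fluid balance via variational flux extraction (an independent
  gradient-based flux check agrees to a few percent).
* **Linear algebra.** Direct sparse factorization (SuperLU); the transport
  operator is factorized once and reused over all steps.  Everything is
  deterministic; rerunning a case reproduces bit-identical metrics.
* **Convergence.** Against the closed-form spherical pressure solution the
  solver is second-order in h and accurate to <0.1% at the defaults; APD
  changes by ~0.002 mm under mesh and time-step refinement (defaults halved
  twice).

## Metric conventions

Profiles are sampled at 401 evenly spaced points per axis (center →
surface) by linear interpolation along the mesh lines that coincide with
the axes.  `LP50` is the normalized distance of the first downward crossing
of half the profile maximum (linearly interpolated); it is dimensionless
because the published range 0.70–0.99 is.  `APD` measures from the surface
to the innermost IC50 crossing; multiple crossings (possible only under
numerical oscillation) use the innermost and log a warning.  The
characteristic length in `Pe = L·u_max/D` is the half-length of the axis of
interest, with a case's single `Pe` being the maximum over axes.  Aggregate
PD% averages weight each emitted (geometry, axis) row equally, spheres
contributing one row; the published small/large group averages appear to
weight the sphere's single axis twice, which shifts the large-group average
by ~0.1 points — both conventions are within the reported tolerance.

## What the parametric cases do and do not show

The geometries are analytic idealizations (no MRI-derived shapes, single
concentric core, homogeneous vasculature) and the surface concentration is
held constant for the whole hour (no instillate depletion), so the
computed depths characterize the transport physics, not any individual
patient nodule.  No protein/ECM binding sink is modeled.  Within those
conditions the study matrices reproduce the expected orderings: smaller
nodules have lower IFP and higher PD%; vascular normalization lowers IFP
and monotonically deepens penetration; cisplatin concentrations dominate
paclitaxel pointwise at equal dose while paclitaxel penetrates deeper by
the IC50 criterion; pressure metrics are invariant under drug swap;
necrotic-core omission and a tenfold permeability change barely move PD%.

## Known limitations

* The absolute baseline penetration depths computed here sit 0.05–0.09 mm
  above the previously published range (0.445–0.507 mm vs 0.36–0.49 mm).
  The solver has been validated against two independent routes (closed-form
  reaction–diffusion profile, and a separate adaptive two-point
  boundary-value integration of the full steady radial physics, agreeing
  to 0.002 mm), and the values are mesh- and step-converged, so the offset
  is attributed to unreported discretization or post-processing details of
  the earlier study — which itself reports the same 0.36 mm extreme for two
  different geometry/axis pairs in different sections.
* The fully normalized small cropped nodule is sensitive to the exact
  placement of the necrotic core: if the drug front just reaches the
  sink-free core the APD jumps through it.  With the construction above the
  viable shell along the short axis is 1.09 mm thick and the front stops
  just short of the interface (PD% ≈ 38 rather than the published 51.6).
  Only the core's two extents are published; placements that pull the core
  slightly deeper into the dome reproduce the larger value.
* Axisymmetric reduction is exact for the shapes used; fully 3D solves are
  out of scope.  Tissue deformation, transient pressure dynamics and
  spatially heterogeneous vascular density are not modeled.
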