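"""Analyzed variables: axis profiles, IFP_max, LP50, APD, PD% and Peclet.

Profiles are sampled along each geometry axis from the nodule center to the
outer surface.  The reported metrics are:

* ``IFP_max``  - maximum nodal interstitial fluid pressure (Pa);
* ``IFV_max``  - maximum Darcy velocity magnitude (m/s);
* ``LP50``     - normalized distance from the center at which the pressure
  profile first drops below 50% of its maximum (profile steepness: the
  steeper the profile, the closer to 1);
* ``APD``      - absolute penetration depth: depth from the outer surface to
  the innermost point where the drug concentration still exceeds the drug's
  IC50 (m);
* ``PD%``      - APD as a percentage of the axis half-length;
* ``Pe``       - global Peclet number ``L * IFV_max / D`` with ``L`` the
  half-length of the axis of interest (convection vs. diffusion balance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from .geometry import Axis, Mesh
from .ifp import PressureField, VelocityField
from .params import DrugParams
from .transport import ConcentrationField

__all__ = [
    "AxisProfile", "AxisMetrics", "CaseMetrics",
    "extract_profile", "lp50", "apd", "pd_percent", "global_peclet",
    "case_metrics",
]


@dataclass
class AxisProfile:
    """Values sampled along one axis, center -> surface."""

    axis: Axis
    positions: np.ndarray          # m from center, strictly increasing
    values: np.ndarray             # Pa or mol/m^3

    @property
    def normalized_positions(self) -> np.ndarray:
        return self.positions / self.axis.half_length


@dataclass
class AxisMetrics:
    axis: str
    half_length: float             # m
    LP50: float
    APD: float                     # m
    PD_percent: float
    Pe: float


@dataclass
class CaseMetrics:
    """All analyzed variables of one solved case."""

    IFP_max: float                 # Pa
    IFV_max: float                 # m/s
    per_axis: Dict[str, AxisMetrics]
    provenance: dict = field(default_factory=dict)

    @property
    def Pe(self) -> float:
        return max(m.Pe for m in self.per_axis.values())

    def rows(self) -> List[dict]:
        out = []
        for name, m in self.per_axis.items():
            out.append({
                **self.provenance,
                "axis": name,
                "IFP_max_Pa": self.IFP_max,
                "IFV_max_m_s": self.IFV_max,
                "LP50": m.LP50,
                "APD_mm": m.APD * 1e3,
                "PD_percent": m.PD_percent,
                "Pe": m.Pe,
            })
        return out


def extract_profile(field_obj, axis: Axis, n_samples: int = 400,
                    time: float | None = None) -> AxisProfile:
    """Sample a solved field along ``axis`` at evenly spaced positions.

    ``field_obj`` is a :class:`PressureField` or :class:`ConcentrationField`
    (for the latter, ``time`` picks a snapshot; default the last).  Values
    are linearly interpolated from the nodal values along the mesh line that
    coincides with the axis.
    """
    if isinstance(field_obj, PressureField):
        mesh, values = field_obj.mesh, field_obj.P
    elif isinstance(field_obj, ConcentrationField):
        mesh = field_obj.mesh
        values = field_obj.final if time is None else field_obj.at_time(time)
    else:
        raise TypeError("field must be a PressureField or ConcentrationField")
    if axis.name not in mesh.axis_lines:
        raise ValueError(
            f"axis {axis.name!r} not on this mesh; available: "
            f"{sorted(mesh.axis_lines)}")
    idx, dist = mesh.axis_lines[axis.name]
    if abs(dist[-1] - axis.half_length) > 1e-9 * axis.half_length:
        raise ValueError("axis half-length does not match the mesh")
    pos = np.linspace(0.0, axis.half_length, n_samples)
    vals = np.interp(pos, dist, values[idx])
    return AxisProfile(axis=axis, positions=pos, values=vals)


def lp50(profile: AxisProfile) -> float:
    """Normalized distance of the 50%-of-maximum pressure crossing.

    Scans from the center outward and linearly interpolates the first
    crossing below half the profile maximum.
    """
    v = profile.values
    p_max = float(v.max())
    if p_max <= 0.0:
        raise ValueError("pressure profile never exceeds 0")
    half = 0.5 * p_max
    x = profile.normalized_positions
    below = np.where(v < half)[0]
    start = int(v.argmax())
    below = below[below > start]
    if below.size == 0:
        return 1.0
    i = int(below[0])
    x0, x1 = x[i - 1], x[i]
    v0, v1 = v[i - 1], v[i]
    return float(x0 + (half - v0) / (v1 - v0) * (x1 - x0))


def apd(profile: AxisProfile, drug: DrugParams) -> float:
    """Absolute penetration depth (m).

    Depth measured inward from the outer surface to the innermost position
    where the concentration still reaches IC50 (linear interpolation at the
    crossing).  Zero when even the surface value is below IC50; equal to the
    axis half-length when the whole profile exceeds IC50.
    """
    c = profile.values
    x = profile.positions
    L = profile.axis.half_length
    above = c >= drug.IC50
    if not above.any():
        return 0.0
    if above.all():
        return float(L)
    i0 = int(np.argmax(above))        # innermost sample above IC50
    if i0 == 0:
        return float(L)
    n_cross = int(np.count_nonzero(np.diff(above.astype(int)) != 0))
    if n_cross > 1:
        warnings.warn("concentration profile crosses IC50 more than once "
                      "(numerical oscillation); using the innermost crossing")
    x0, x1 = x[i0 - 1], x[i0]
    c0, c1 = c[i0 - 1], c[i0]
    x_star = x0 + (drug.IC50 - c0) / (c1 - c0) * (x1 - x0)
    return float(L - x_star)


def pd_percent(apd_value: float, axis: Axis) -> float:
    """Relative penetration depth, percent of the axis half-length."""
    if apd_value > axis.half_length * (1 + 1e-9):
        raise ValueError("APD exceeds the axis half-length")
    return 100.0 * apd_value / axis.half_length


def global_peclet(axis: Axis, vel: VelocityField, drug: DrugParams) -> float:
    """Global Peclet number ``Pe = L * u_max / D`` for one axis.

    ``L`` is the half-length of the axis of interest and ``u_max`` the
    maximal interstitial fluid velocity magnitude of the case.
    """
    if drug.D <= 0:
        raise ValueError("D must be > 0")
    return axis.half_length * vel.IFV_max / drug.D


def case_metrics(press: PressureField, vel: VelocityField,
                 conc: ConcentrationField, drug: DrugParams,
                 axes: List[Axis], n_samples: int = 400,
                 provenance: dict | None = None) -> CaseMetrics:
    """Assemble the full analyzed-variable set for one solved case."""
    per_axis: Dict[str, AxisMetrics] = {}
    for ax in axes:
        p_prof = extract_profile(press, ax, n_samples)
        c_prof = extract_profile(conc, ax, n_samples)
        apd_val = apd(c_prof, drug)
        per_axis[ax.name] = AxisMetrics(
            axis=ax.name,
            half_length=ax.half_length,
            LP50=lp50(p_prof),
            APD=apd_val,
            PD_percent=pd_percent(apd_val, ax),
            Pe=global_peclet(ax, vel, drug),
        )
    return CaseMetrics(
        IFP_max=float(press.P.max()),
        IFV_max=vel.IFV_max,
        per_axis=per_axis,
        provenance=provenance or {},
    )
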