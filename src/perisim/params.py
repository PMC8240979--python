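"""Physical parameters, presets and unit handling.

All quantities are stored internally in SI units (m, s, Pa, mol/m^3); printed
table values in other units (e.g. vessel-wall permeability in cm/s) are
converted once at the parsing boundary by :func:`to_si`.

The tumor-tissue baseline describes a vascularized solid tumor: a leaky
microvasculature (hydraulic conductivity ``L_p``, surface-to-volume ratio
``S/V``) filters plasma into the interstitium against the osmotic pressure
difference, there is no functional lymphatic drainage, and the interstitium
behaves as a rigid porous medium with Darcy conductivity ``K = k/mu``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import Mapping

__all__ = [
    "TissueParams",
    "DrugParams",
    "GeometrySpec",
    "BASELINE_TISSUE",
    "NORMAL_VASCULATURE",
    "DRUGS",
    "GEOMETRIES",
    "PERMEABILITY_SWEEP_M2",
    "preset",
    "to_si",
    "tissue_from_printed",
    "drug_from_printed",
    "normalize_vasculature",
    "effective_pressure",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueParams:
    """Tissue and vascular transport properties (SI units).

    Parameters
    ----------
    K : float
        Hydraulic conductivity of the interstitium, m^2/(Pa s).
    k_intrinsic : float
        Intrinsic (Darcy) permeability, m^2.  Tied to ``K`` by ``K = k/mu``.
    mu : float
        Interstitial fluid dynamic viscosity, Pa s.
    L_p : float
        Hydraulic conductivity of the vessel walls, m/(Pa s).
    S_over_V : float
        Vascular surface-to-volume ratio, 1/m.
    P_v : float
        Vascular (capillary) pressure, Pa.
    pi_v, pi_i : float
        Vascular and interstitial osmotic pressures, Pa.
    c_osm : float
        Osmotic reflection coefficient of the vessel wall (dimensionless).
    rho : float
        Fluid density, kg/m^3.  Metadata only: the flow model is
        incompressible and never uses it.
    """

    K: float = 3.10e-14
    k_intrinsic: float = 3.10e-17
    mu: float = 1.00e-3
    L_p: float = 2.10e-11
    S_over_V: float = 2.00e4
    P_v: float = 2.08e3
    pi_v: float = 2.67e3
    pi_i: float = 2.00e3
    c_osm: float = 0.82
    rho: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("K", "k_intrinsic", "mu", "L_p", "S_over_V", "P_v",
                     "pi_v", "pi_i", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TissueParams.{name} must be > 0")
        if not 0.0 <= self.c_osm <= 1.0:
            raise ValueError("c_osm must lie in [0, 1]")
        if abs(self.K * self.mu - self.k_intrinsic) > 0.01 * self.k_intrinsic:
            raise ValueError(
                "inconsistent Darcy parameters: K*mu = "
                f"{self.K * self.mu:.3e} differs from k_intrinsic = "
                f"{self.k_intrinsic:.3e} by more than 1%"
            )

    def with_permeability(self, k_intrinsic: float) -> "TissueParams":
        """Return a copy with intrinsic permeability ``k`` and ``K = k/mu``."""
        return replace(self, k_intrinsic=k_intrinsic, K=k_intrinsic / self.mu)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DrugParams:
    """Drug transport and pharmacodynamic properties (SI units).

    ``MW`` (molecular weight, g/mol) is stored for provenance only; the model
    uses the interstitial diffusivity ``D`` directly.
    """

    name: str
    D: float
    beta: float
    sigma: float
    P_c: float
    IC50: float
    C0: float
    MW: float = 300.0

    def __post_init__(self) -> None:
        for fname in ("D", "beta", "P_c", "IC50", "C0"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"DrugParams.{fname} must be > 0")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("sigma must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GeometrySpec:
    """Parametric nodule geometry.

    ``shape`` is one of ``sphere`` (radius ``r_l == r_s``), ``ellipsoid``
    (prolate spheroid, half-axes ``r_l`` along the long axis, ``r_s``
    transverse) or ``cropped`` (the ellipsoid cut by a plane through its
    center parallel to the long axis, leaving a dome of in-plane half-length
    ``r_l`` and depth ``r_s``).  The necrotic core is a similarly shaped,
    concentric inner surface with half-lengths ``r_ln``/``r_sn``.
    """

    shape: str
    r_l: float
    r_s: float
    r_ln: float = 0.0
    r_sn: float = 0.0
    has_necrotic_core: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid", "cropped"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not (0.0 <= self.r_ln < self.r_l and 0.0 <= self.r_sn < self.r_s):
            raise ValueError("necrotic half-lengths must satisfy 0 <= r_n < r")
        if self.shape == "sphere" and self.r_l != self.r_s:
            raise ValueError("sphere requires r_l == r_s")
        if self.has_necrotic_core and (self.r_ln == 0.0) != (self.r_sn == 0.0):
            raise ValueError("necrotic core needs both half-lengths > 0")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Presets (baseline tables)
# ---------------------------------------------------------------------------

BASELINE_TISSUE = TissueParams()

#: Normal-tissue endpoints of the vascular-normalization interpolation.
NORMAL_VASCULATURE = {"L_p": 2.70e-12, "S_over_V": 7.00e3, "c_osm": 0.91}

DRUGS: Mapping[str, DrugParams] = {
    "cisplatin": DrugParams(
        name="cisplatin", D=2.5e-10, beta=7.32e-4, sigma=8.17e-5,
        P_c=1.43e-6, IC50=6.2e-3, C0=0.8, MW=300.0,
    ),
    "paclitaxel": DrugParams(
        name="paclitaxel", D=0.77e-10, beta=7.32e-4, sigma=8.17e-5,
        P_c=1.43e-6, IC50=1.4e-6, C0=0.8, MW=300.0,
    ),
}

GEOMETRIES: Mapping[str, GeometrySpec] = {
    # large nodules
    "LS": GeometrySpec("sphere", 0.010, 0.010, 0.005, 0.005, True, "LS"),
    "LE": GeometrySpec("ellipsoid", 0.020, 0.010, 0.010, 0.005, True, "LE"),
    "LT": GeometrySpec("cropped", 0.020, 0.010, 0.0087, 0.00453, True, "LT"),
    # the same shapes scaled down by a factor 5
    "SS": GeometrySpec("sphere", 0.002, 0.002, 0.001, 0.001, True, "SS"),
    "SE": GeometrySpec("ellipsoid", 0.004, 0.002, 0.002, 0.001, True, "SE"),
    "ST": GeometrySpec("cropped", 0.004, 0.002, 0.00174, 0.000906, True, "ST"),
}

#: Intrinsic permeability sweep, m^2 (normal tissue, common tumor value, and
#: the third literature value).
PERMEABILITY_SWEEP_M2 = (6.4e-18, 3.1e-17, 6.4e-17)


def preset(case_label: str, drug: str = "cisplatin"):
    """Return ``(TissueParams, DrugParams, GeometrySpec)`` for a named case.

    ``case_label`` is one of LS/LE/LT/SS/SE/ST; ``drug`` is ``cisplatin`` or
    ``paclitaxel``.  Tissue values are the baseline table; the two drugs
    differ only in diffusivity and IC50.
    """
    if case_label not in GEOMETRIES:
        raise ValueError(
            f"unknown geometry label {case_label!r}; "
            f"valid labels: {sorted(GEOMETRIES)}"
        )
    if drug not in DRUGS:
        raise ValueError(
            f"unknown drug {drug!r}; valid drugs: {sorted(DRUGS)}"
        )
    return BASELINE_TISSUE, DRUGS[drug], GEOMETRIES[case_label]


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

#: Multiplicative factors from printed units to SI.
_UNIT_FACTORS = {
    "m": 1.0,
    "mm": 1e-3,
    "cm": 1e-2,
    "m/s": 1.0,
    "cm/s": 1e-2,
    "mm/s": 1e-3,
    "m2": 1.0,
    "m^2": 1.0,
    "m2/s": 1.0,
    "m^2/s": 1.0,
    "Pa": 1.0,
    "kPa": 1e3,
    "mmHg": 133.322,
    "Pa s": 1.0,
    "m/Pa s": 1.0,
    "m2/Pa s": 1.0,
    "m^2/Pa s": 1.0,
    "1/m": 1.0,
    "1/s": 1.0,
    "kg/m3": 1.0,
    "kg/m^3": 1.0,
    "mol/m3": 1.0,
    "mol/m^3": 1.0,
    "g/mol": 1.0,
    "-": 1.0,
    "": 1.0,
}


def to_si(value: float, unit: str) -> float:
    """Convert a printed ``(value, unit)`` pair to SI.

    Raises ``ValueError`` for an unknown or missing unit string; units are
    never silently assumed.
    """
    if unit is None:
        raise ValueError("missing unit string")
    key = unit.strip()
    if key not in _UNIT_FACTORS:
        raise ValueError(f"unrecognized unit {unit!r}")
    return value * _UNIT_FACTORS[key]


_TISSUE_FIELDS = ("K", "k_intrinsic", "mu", "L_p", "S_over_V", "P_v",
                  "pi_v", "pi_i", "c_osm", "rho")
_DRUG_FIELDS = ("D", "beta", "sigma", "P_c", "IC50", "C0", "MW")


def tissue_from_printed(rows: Mapping[str, tuple]) -> TissueParams:
    """Build :class:`TissueParams` from ``{field: (value, unit)}`` rows."""
    si = {f: to_si(*rows[f]) for f in _TISSUE_FIELDS if f in rows}
    return replace(BASELINE_TISSUE, **si)


def drug_from_printed(name: str, rows: Mapping[str, tuple]) -> DrugParams:
    """Build :class:`DrugParams` from ``{field: (value, unit)}`` rows."""
    si = {f: to_si(*rows[f]) for f in _DRUG_FIELDS if f in rows}
    base = DRUGS.get(name)
    if base is None:
        missing = [f for f in _DRUG_FIELDS if f not in si and f != "MW"]
        if missing:
            raise ValueError(f"missing drug parameters for {name!r}: {missing}")
        return DrugParams(name=name, **si)
    return replace(base, **si)


# ---------------------------------------------------------------------------
# Derived operations
# ---------------------------------------------------------------------------

def normalize_vasculature(base: TissueParams, fraction: float) -> TissueParams:
    """Interpolate vascular properties toward normal tissue.

    ``fraction = 0`` returns the tumor baseline; ``fraction = 1`` the
    normal-tissue endpoints; intermediate values interpolate ``L_p``,
    ``S/V`` and the osmotic reflection coefficient linearly (vascular
    normalization therapy shifts all three together).  Non-vascular fields
    are unchanged.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("normalization fraction must lie in [0, 1]")
    interp = {
        field: (1.0 - fraction) * getattr(base, field) + fraction * target
        for field, target in NORMAL_VASCULATURE.items()
    }
    return replace(base, **interp)


def effective_pressure(tissue: TissueParams) -> float:
    """Steady-state effective vascular pressure ``P_ss`` (Pa).

    The zero of the Starling filtration source:
    ``P_ss = P_v - c_osm * (pi_v - pi_i)``.  It is the supremum of the
    interstitial fluid pressure attainable with a zero-pressure surface.
    """
    return tissue.P_v - tissue.c_osm * (tissue.pi_v - tissue.pi_i)
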