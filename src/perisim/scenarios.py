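"""Study matrix: baselines, drug comparison, vascular normalization,
necrotic-core omission and permeability sweep.

``run_case`` executes the full segregated pipeline for one configuration
(mesh -> steady pressure -> Darcy velocity -> transient + steady transport ->
metrics); ``run_study`` assembles the named study matrices and their
comparison tables against the matched baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import List, Optional

import numpy as np
import pandas as pd

from . import geometry, ifp, metrics, transport
from .params import (DRUGS, GEOMETRIES, PERMEABILITY_SWEEP_M2, preset,
                     normalize_vasculature)

__all__ = [
    "Scenario", "SolverSettings", "CaseResult", "StudyResult",
    "run_case", "run_study", "summarize",
    "SMALL_GROUP", "LARGE_GROUP", "STUDIES",
]

SMALL_GROUP = ("SS", "SE", "ST")
LARGE_GROUP = ("LS", "LE", "LT")
STUDIES = ("baseline", "drug", "normalization", "necrotic", "permeability")


@dataclass(frozen=True)
class Scenario:
    """One entry of the study matrix."""

    geometry: str
    drug: str = "cisplatin"
    normalization_fraction: float = 0.0
    necrotic_core: bool = True
    k_intrinsic: Optional[float] = None      # m^2 override
    C0: Optional[float] = None               # mol/m^3 override
    t_end: float = 3600.0                    # s, transient evaluation time
    dt: float = 30.0                         # s

    def label(self) -> str:
        parts = [self.geometry, self.drug]
        if self.normalization_fraction:
            parts.append(f"norm{int(self.normalization_fraction * 100)}")
        if not self.necrotic_core:
            parts.append("nocore")
        if self.k_intrinsic is not None:
            parts.append(f"k{self.k_intrinsic:.1e}")
        if self.C0 is not None:
            parts.append(f"C0{self.C0:g}")
        return "-".join(parts)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings (version-pinned defaults for reproducible tables)."""

    target_h: Optional[float] = None     # surface-layer spacing, m
    n_theta: int = 96
    n_inner: int = 24
    n_samples: int = 401                 # profile samples per axis
    store_every: int = 4                 # snapshot cadence (in steps)
    flat_face_dirichlet: bool = False
    compute_steady: bool = True


@dataclass
class CaseResult:
    scenario: Scenario
    mesh: geometry.Mesh
    pressure: ifp.PressureField
    velocity: ifp.VelocityField
    conc: transport.ConcentrationField
    conc_steady: Optional[transport.ConcentrationField]
    metrics: metrics.CaseMetrics
    metrics_steady: Optional[metrics.CaseMetrics]
    drug: object
    tissue: object
    axes: list


@dataclass
class StudyResult:
    name: str
    cases: List[CaseResult]
    table: pd.DataFrame
    deltas: Optional[pd.DataFrame] = None


def _materialize(s: Scenario, geometry_spec=None, drug_params=None,
                 tissue_overrides=None):
    from .params import BASELINE_TISSUE
    if geometry_spec is None or drug_params is None:
        tissue, drug, geom = preset(
            s.geometry if geometry_spec is None else "LS", s.drug
            if drug_params is None else "cisplatin")
    else:
        tissue = BASELINE_TISSUE
    if geometry_spec is not None:
        geom = geometry_spec
    if drug_params is not None:
        drug = drug_params
    if tissue_overrides:
        tissue = replace(tissue, **tissue_overrides)
    if s.k_intrinsic is not None:
        tissue = tissue.with_permeability(s.k_intrinsic)
    if s.normalization_fraction:
        tissue = normalize_vasculature(tissue, s.normalization_fraction)
    if s.C0 is not None:
        drug = replace(drug, C0=s.C0)
    if not s.necrotic_core:
        geom = replace(geom, has_necrotic_core=False)
    return tissue, drug, geom


def run_case(s: Scenario, settings: SolverSettings | None = None, *,
             geometry_spec=None, drug_params=None,
             tissue_overrides=None) -> CaseResult:
    """Run the segregated pipeline for one scenario (deterministic).

    ``geometry_spec``/``drug_params``/``tissue_overrides`` allow explicit
    objects from a configuration file to replace the named presets.
    """
    settings = settings or SolverSettings()
    tissue, drug, geom = _materialize(s, geometry_spec, drug_params,
                                      tissue_overrides)
    mesh = geometry.build_mesh(
        geom, settings.target_h, n_theta=settings.n_theta,
        n_inner=settings.n_inner,
        flat_face_dirichlet=settings.flat_face_dirichlet)
    press = ifp.solve_ifp(mesh, tissue)
    vel = ifp.velocity_from_pressure(press, tissue)
    conc = transport.solve_transport(
        mesh, vel, press, drug, tissue,
        t_end=s.t_end, dt=s.dt, store_every=settings.store_every)
    axes = geometry.axes_of(geom)
    prov = {"case": s.label(), "geometry": s.geometry, "drug": s.drug,
            "scenario": s.to_dict(), "eval_time_s": s.t_end}
    mets = metrics.case_metrics(press, vel, conc, drug, axes,
                                n_samples=settings.n_samples, provenance=prov)
    conc_ss = mets_ss = None
    if settings.compute_steady:
        conc_ss = transport.steady_transport(mesh, vel, press, drug, tissue)
        prov_ss = {**prov, "eval_time_s": np.inf}
        mets_ss = metrics.case_metrics(press, vel, conc_ss, drug, axes,
                                       n_samples=settings.n_samples,
                                       provenance=prov_ss)
    return CaseResult(s, mesh, press, vel, conc, conc_ss, mets, mets_ss,
                      drug, tissue, axes)


def _scenarios_for(name: str) -> List[Scenario]:
    geoms = list(GEOMETRIES)
    if name == "baseline":
        return [Scenario(g) for g in geoms]
    if name == "drug":
        out = [Scenario(g, d) for g in geoms for d in DRUGS]
        # clinical-dose paclitaxel on the 10 mm sphere (60 mg/m^2)
        out.append(Scenario("LS", "paclitaxel", C0=0.14))
        return out
    if name == "normalization":
        return [Scenario(g, normalization_fraction=f)
                for g in geoms for f in (0.0, 0.5, 1.0)]
    if name == "necrotic":
        return [Scenario(g, necrotic_core=core)
                for g in geoms for core in (True, False)]
    if name == "permeability":
        return [Scenario(g, k_intrinsic=k)
                for g in geoms for k in PERMEABILITY_SWEEP_M2]
    raise ValueError(f"unknown study {name!r}; valid: {STUDIES}")


def _is_baseline(s: Scenario) -> bool:
    return (s.normalization_fraction == 0.0 and s.necrotic_core
            and (s.k_intrinsic is None or s.k_intrinsic == 3.1e-17)
            and s.C0 is None and s.drug == "cisplatin")


def _rows(case: CaseResult, steady: bool = False) -> List[dict]:
    m = case.metrics_steady if steady else case.metrics
    rows = []
    for r in m.rows():
        r.pop("scenario", None)
        rows.append(r)
    return rows


def run_study(name: str, settings: SolverSettings | None = None) -> StudyResult:
    """Run a named study and build its metric and comparison tables."""
    scenarios = _scenarios_for(name)
    cases = [run_case(s, settings) for s in scenarios]
    rows = []
    for c in cases:
        rows.extend(_rows(c))
    table = pd.DataFrame(rows)

    deltas = None
    if name != "baseline":
        base = {}
        for c in cases:
            if _is_baseline(c.scenario):
                for ax, am in c.metrics.per_axis.items():
                    base[(c.scenario.geometry, ax)] = (am, c.metrics.IFP_max)
        if not base:  # studies whose baseline member is parameterized away
            for s in [Scenario(g) for g in GEOMETRIES]:
                c = run_case(s, settings)
                for ax, am in c.metrics.per_axis.items():
                    base[(s.geometry, ax)] = (am, c.metrics.IFP_max)
        drows = []
        for c in cases:
            if _is_baseline(c.scenario):
                continue
            for ax, am in c.metrics.per_axis.items():
                bm, b_ifp = base[(c.scenario.geometry, ax)]
                drows.append({
                    "case": c.scenario.label(),
                    "geometry": c.scenario.geometry,
                    "axis": ax,
                    "delta_APD_mm": (am.APD - bm.APD) * 1e3,
                    "delta_PD_percent": am.PD_percent - bm.PD_percent,
                    "rel_PD_percent": (
                        100.0 * (am.PD_percent - bm.PD_percent)
                        / bm.PD_percent if bm.PD_percent else np.nan),
                    "delta_IFP_max_Pa": c.metrics.IFP_max - b_ifp,
                })
        deltas = pd.DataFrame(drows)
    return StudyResult(name=name, cases=cases, table=table, deltas=deltas)


def summarize(result: StudyResult) -> dict:
    """Aggregate a study: size-group PD% and IFP_max averages, APD extremes.

    PD% is averaged with equal weight per (geometry, axis) row; IFP_max with
    equal weight per geometry.
    """
    t = result.table
    if t.empty:
        raise ValueError("empty study result")
    out = {}
    for gname, members in (("small", SMALL_GROUP), ("large", LARGE_GROUP)):
        sub = t[t.geometry.isin(members)]
        if sub.empty:
            continue
        out[f"PD_percent_average_{gname}"] = float(sub.PD_percent.mean())
        per_geom = sub.groupby("geometry").IFP_max_Pa.first()
        out[f"IFP_max_average_{gname}_Pa"] = float(per_geom.mean())
    i_min = t.APD_mm.idxmin()
    i_max = t.APD_mm.idxmax()
    out["APD_min_mm"] = float(t.APD_mm[i_min])
    out["APD_min_case"] = f"{t.axis[i_min]}-{t.geometry[i_min]}"
    out["APD_max_mm"] = float(t.APD_mm[i_max])
    out["APD_max_case"] = f"{t.axis[i_max]}-{t.geometry[i_max]}"
    return out
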