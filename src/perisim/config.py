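"""YAML configuration parsing for scenario and solver settings.

See ``docs/config_schema.md`` for every key, its unit and default.  All
values are given in SI units; unknown keys raise rather than being ignored.
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .params import DRUGS, GEOMETRIES, DrugParams, GeometrySpec
from .scenarios import Scenario, SolverSettings

__all__ = ["load_config", "scenario_from_dict"]

_SCENARIO_KEYS = {"geometry", "drug", "normalization_fraction",
                  "necrotic_core", "k_intrinsic", "C0", "t_end", "dt",
                  "tissue_overrides"}
_SOLVER_KEYS = {"target_h", "n_theta", "n_inner", "n_samples", "store_every",
                "flat_face_dirichlet", "compute_steady"}


def scenario_from_dict(cfg: dict) -> tuple[Scenario, SolverSettings, dict]:
    """Build (Scenario, SolverSettings, extras) from a config mapping.

    ``geometry`` may be a preset label or an explicit mapping (shape and
    half-lengths); ``drug`` a preset name or an explicit parameter mapping.
    Explicit geometry/drug objects are returned in ``extras``.
    """
    unknown = set(cfg) - _SCENARIO_KEYS - {"solver"}
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    extras: dict = {}

    geom_cfg = cfg.get("geometry", "LS")
    if isinstance(geom_cfg, str):
        if geom_cfg not in GEOMETRIES:
            raise ValueError(f"unknown geometry label {geom_cfg!r}")
        geom_label = geom_cfg
    else:
        spec = GeometrySpec(**geom_cfg)
        extras["geometry_spec"] = spec
        geom_label = spec.label or "custom"

    drug_cfg = cfg.get("drug", "cisplatin")
    if isinstance(drug_cfg, str):
        if drug_cfg not in DRUGS:
            raise ValueError(f"unknown drug {drug_cfg!r}")
        drug_name = drug_cfg
    else:
        drug = DrugParams(**drug_cfg)
        extras["drug_params"] = drug
        drug_name = drug.name

    if "tissue_overrides" in cfg:
        extras["tissue_overrides"] = dict(cfg["tissue_overrides"])

    scenario = Scenario(
        geometry=geom_label,
        drug=drug_name,
        normalization_fraction=float(cfg.get("normalization_fraction", 0.0)),
        necrotic_core=bool(cfg.get("necrotic_core", True)),
        k_intrinsic=cfg.get("k_intrinsic"),
        C0=cfg.get("C0"),
        t_end=float(cfg.get("t_end", 3600.0)),
        dt=float(cfg.get("dt", 30.0)),
    )
    solver_cfg = cfg.get("solver", {})
    unknown = set(solver_cfg) - _SOLVER_KEYS
    if unknown:
        raise ValueError(f"unknown solver keys: {sorted(unknown)}")
    settings = replace(SolverSettings(), **solver_cfg)
    return scenario, settings, extras


def load_config(path: str) -> tuple[Scenario, SolverSettings, dict]:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    return scenario_from_dict(cfg)
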