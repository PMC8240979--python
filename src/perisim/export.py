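"""Plain-text exports: profile/metric CSV files and legacy-ASCII VTK fields.

The VTK writer emits minimal legacy unstructured-grid files (points, cells,
cell/point data) readable by ParaView; only ASCII output is produced so all
artifacts stay text.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .geometry import Mesh
from .metrics import AxisProfile

__all__ = ["profile_to_csv", "metrics_to_csv", "write_vtk"]


def profile_to_csv(profile: AxisProfile, path: str, kind: str = "pressure",
                   normalizer: float | None = None) -> None:
    """Write an axis profile as CSV.

    Columns: distance_m, normalized_distance, value, normalized_value with
    the value column named ``P_Pa`` or ``C_mol_per_m3`` by ``kind``.
    """
    name = "P_Pa" if kind == "pressure" else "C_mol_per_m3"
    ref = normalizer if normalizer else (float(np.max(profile.values)) or 1.0)
    df = pd.DataFrame({
        "distance_m": profile.positions,
        "normalized_distance": profile.normalized_positions,
        name: profile.values,
        f"normalized_{name.split('_')[0]}": profile.values / ref,
    })
    df.to_csv(path, index=False)


def metrics_to_csv(table: pd.DataFrame, path: str) -> None:
    cols = ["case", "geometry", "drug", "axis", "IFP_max_Pa", "IFV_max_m_s",
            "LP50", "APD_mm", "PD_percent", "Pe", "eval_time_s"]
    table[[c for c in cols if c in table.columns]].to_csv(path, index=False)


def write_vtk(mesh: Mesh, path: str, point_data: dict | None = None,
              cell_data: dict | None = None, title: str = "perisim") -> None:
    """Write the mesh and fields as a legacy-ASCII VTK unstructured grid."""
    point_data = point_data or {}
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.region.astype(float))
    if mesh.mode == "radial_1d":
        pts = np.column_stack([mesh.nodes, np.zeros_like(mesh.nodes),
                               np.zeros_like(mesh.nodes)])
        ncols, vtk_type = 2, 3          # VTK_LINE
    else:
        pts = np.column_stack([mesh.nodes, np.zeros(mesh.n_nodes)])
        ncols, vtk_type = 3, 5          # VTK_TRIANGLE
    cells = mesh.cells
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {pts.shape[0]} double\n")
        np.savetxt(f, pts, fmt="%.9e")
        f.write(f"CELLS {cells.shape[0]} {cells.shape[0] * (ncols + 1)}\n")
        np.savetxt(f, np.column_stack(
            [np.full(cells.shape[0], ncols), cells]), fmt="%d")
        f.write(f"CELL_TYPES {cells.shape[0]}\n")
        np.savetxt(f, np.full(cells.shape[0], vtk_type), fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {pts.shape[0]}\n")
            for name, arr in point_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, np.asarray(arr, dtype=float), fmt="%.9e")
        if cell_data:
            f.write(f"CELL_DATA {cells.shape[0]}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.9e")
                else:
                    f.write(f"VECTORS {name} double\n")
                    vec3 = np.zeros((arr.shape[0], 3))
                    vec3[:, :arr.shape[1]] = arr
                    np.savetxt(f, vec3, fmt="%.9e")
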