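# Configuration file schema

`perisim run-case --config FILE` accepts a YAML mapping.  All physical
values are SI.  Unknown keys are rejected.

## Top-level keys

| key | type / values | unit | default | meaning |
|-----|---------------|------|---------|---------|
| `geometry` | label `LS/LE/LT/SS/SE/ST` or mapping (below) | — | `LS` | nodule geometry |
| `drug` | name `cisplatin`/`paclitaxel` or mapping (below) | — | `cisplatin` | drug parameter set |
| `normalization_fraction` | float in [0, 1] | — | `0.0` | vascular normalization: 0 = tumor baseline, 1 = normal-tissue vasculature |
| `necrotic_core` | bool | — | `true` | `false` treats the core region as viable tissue (same mesh) |
| `k_intrinsic` | float | m² | preset `3.1e-17` | intrinsic permeability override; `K` is recomputed as `k/μ` |
| `C0` | float | mol/m³ | drug preset (0.8) | surface (instillate) concentration override |
| `t_end` | float | s | `3600` | transient evaluation time |
| `dt` | float | s | `30` | time-step size |
| `tissue_overrides` | mapping field → value | SI | — | overrides for individual `TissueParams` fields |
| `solver` | mapping (below) | — | — | numerical settings |

## `geometry` as an explicit mapping

Fields of `GeometrySpec`: `shape` (`sphere`/`ellipsoid`/`cropped`), `r_l`,
`r_s`, `r_ln`, `r_sn` (m, half-lengths; `r_s` is the depth for cropped
shapes), `has_necrotic_core` (bool), `label` (text).

## `drug` as an explicit mapping

Fields of `DrugParams`: `name`, `D` (m²/s), `beta` (1/s), `sigma` (—),
`P_c` (m/s), `IC50` (mol/m³), `C0` (mol/m³), `MW` (g/mol, metadata).

## `solver` keys

| key | type | unit | default | meaning |
|-----|------|------|---------|---------|
| `target_h` | float | m | `3e-6` (1D) / `8e-6` (2D) | radial spacing at the outer surface |
| `n_theta` | int | — | `96` | angular columns of the axisymmetric mesh |
| `n_inner` | int | — | `24` | radial levels inside the core band |
| `n_samples` | int | — | `401` | profile samples per axis |
| `store_every` | int | — | `4` | snapshot cadence in time steps |
| `flat_face_dirichlet` | bool | — | `false` | apply the surface pressure/concentration condition on the flat face of cropped nodules |
| `compute_steady` | bool | — | `true` | also solve the steady transport problem |

## Example

```yaml
geometry: ST
drug: cisplatin
normalization_fraction: 1.0
t_end: 3600
solver:
  n_theta: 128
```
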