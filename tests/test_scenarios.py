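"""Study pipeline: determinism, study matrices, comparisons, CLI."""

import json
import os

import numpy as np
import pytest

from perisim.config import scenario_from_dict
from perisim.scenarios import (Scenario, SolverSettings, run_case, run_study,
                               summarize)


class TestRunCase:
    def test_deterministic_reruns(self):
        a = run_case(Scenario("SS"))
        b = run_case(Scenario("SS"))
        assert a.metrics.IFP_max == b.metrics.IFP_max
        assert np.array_equal(a.conc.final, b.conc.final)
        for ax in a.metrics.per_axis:
            assert a.metrics.per_axis[ax].APD == b.metrics.per_axis[ax].APD

    def test_pressure_invariant_under_drug_swap(self, baseline_cases,
                                                paclitaxel_cases):
        for g, case in baseline_cases.items():
            other = paclitaxel_cases[g]
            assert case.metrics.IFP_max == other.metrics.IFP_max
            for ax in case.metrics.per_axis:
                assert case.metrics.per_axis[ax].LP50 \
                    == other.metrics.per_axis[ax].LP50

    def test_cisplatin_concentration_dominates_paclitaxel(
            self, baseline_cases, paclitaxel_cases):
        # equal boundary concentration, higher diffusivity: cisplatin is
        # higher everywhere at all stored times, yet paclitaxel penetrates
        # deeper by the IC50 criterion (its IC50 is ~4500x smaller)
        for g in baseline_cases:
            cis, pac = baseline_cases[g], paclitaxel_cases[g]
            assert np.all(cis.conc.C >= pac.conc.C - 1e-12)
            for ax in cis.metrics.per_axis:
                assert pac.metrics.per_axis[ax].APD \
                    >= cis.metrics.per_axis[ax].APD

    def test_smaller_nodules_penetrate_deeper_relative(self, baseline_cases):
        for small, large in (("SS", "LS"), ("SE", "LE"), ("ST", "LT")):
            for ax in baseline_cases[small].metrics.per_axis:
                assert baseline_cases[small].metrics.per_axis[ax].PD_percent \
                    >= baseline_cases[large].metrics.per_axis[ax].PD_percent


class TestStudies:
    def test_baseline_study_row_count(self):
        res = run_study("baseline")
        # 1 axis x 2 spheres + 2 axes x 4 other geometries
        assert len(res.table) == 10
        assert res.deltas is None

    def test_unknown_study_rejected(self):
        with pytest.raises(ValueError):
            run_study("banana")

    def test_necrotic_core_omission_is_minor(self):
        res = run_study("necrotic")
        assert res.deltas is not None
        # matched baseline row exists for every non-baseline row
        assert len(res.deltas) == 10
        assert res.deltas.delta_PD_percent.abs().max() <= 3.56 + 1.5

    def test_normalization_monotone_improvement(self):
        res = run_study("normalization")
        t = res.table
        for g in t.geometry.unique():
            for ax in t[t.geometry == g].axis.unique():
                sel = t[(t.geometry == g) & (t.axis == ax)]
                apds = [
                    float(sel[sel.case.str.contains("norm50")].APD_mm.iloc[0])
                    if n == 50 else
                    float(sel[sel.case.str.contains("norm100")].APD_mm.iloc[0])
                    if n == 100 else
                    float(sel[~sel.case.str.contains("norm")].APD_mm.iloc[0])
                    for n in (0, 50, 100)
                ]
                assert apds[0] <= apds[1] <= apds[2]

    def test_summary_aggregates(self, baseline_cases):
        import pandas as pd
        from perisim.scenarios import StudyResult
        rows = []
        for case in baseline_cases.values():
            for r in case.metrics.rows():
                r.pop("scenario", None)
                rows.append(r)
        res = StudyResult("baseline", list(baseline_cases.values()),
                          pd.DataFrame(rows))
        summary = summarize(res)
        assert set(summary) >= {"PD_percent_average_small",
                                "PD_percent_average_large",
                                "IFP_max_average_small_Pa", "APD_min_mm"}
        # single-case summary equals the case's own values
        single = StudyResult("one", [baseline_cases["LS"]],
                             pd.DataFrame(rows[:1]))
        s1 = summarize(single)
        assert s1["PD_percent_average_large"] == pytest.approx(
            rows[0]["PD_percent"])


class TestConfig:
    def test_label_config_roundtrip(self):
        s, settings, extras = scenario_from_dict({
            "geometry": "SE", "drug": "paclitaxel",
            "normalization_fraction": 0.5, "t_end": 1800,
            "solver": {"n_theta": 48},
        })
        assert s.geometry == "SE" and s.drug == "paclitaxel"
        assert s.normalization_fraction == 0.5 and s.t_end == 1800.0
        assert settings.n_theta == 48

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            scenario_from_dict({"geometri": "LS"})
        with pytest.raises(ValueError, match="unknown"):
            scenario_from_dict({"solver": {"mesh_size": 1}})

    def test_explicit_geometry_and_drug(self):
        s, _, extras = scenario_from_dict({
            "geometry": {"shape": "sphere", "r_l": 0.005, "r_s": 0.005,
                         "r_ln": 0.002, "r_sn": 0.002, "label": "custom"},
            "drug": {"name": "carboplatin", "D": 2.0e-10, "beta": 7.32e-4,
                     "sigma": 8.17e-5, "P_c": 1.43e-6, "IC50": 5e-3,
                     "C0": 0.8},
        })
        assert extras["geometry_spec"].r_l == 0.005
        assert extras["drug_params"].name == "carboplatin"


    def test_config_driven_run(self, tmp_path):
        from perisim.config import load_config
        from perisim.scenarios import run_case
        cfg = tmp_path / "case.yaml"
        cfg.write_text(
            "geometry: {shape: sphere, r_l: 0.001, r_s: 0.001,\n"
            "  r_ln: 0.0, r_sn: 0.0, has_necrotic_core: false, label: tiny}\n"
            "drug: cisplatin\n"
            "t_end: 300\n"
            "tissue_overrides: {L_p: 1.0e-11}\n")
        scenario, settings, extras = load_config(str(cfg))
        case = run_case(scenario, settings, **extras)
        assert case.tissue.L_p == 1.0e-11
        assert case.mesh.spec.r_l == 0.001
        assert case.metrics.IFP_max > 0


class TestCLI:
    def test_run_case_writes_outputs(self, tmp_path):
        from click.testing import CliRunner
        from perisim.cli import main
        out = tmp_path / "out"
        result = CliRunner().invoke(main, [
            "run-case", "--geometry", "SS", "--t-end", "300",
            "--out", str(out), "--vtk"])
        assert result.exit_code == 0, result.output
        assert (out / "metrics.csv").exists()
        assert (out / "manifest.json").exists()
        assert any(p.suffix == ".vtk" for p in out.iterdir())
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["scenario"]["geometry"] == "SS"
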