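"""Workflow orchestration, volume round trips, manifests, CLI smoke."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import bnctcheck as bc
from bnctcheck.cli import main as cli_main
from bnctcheck.dosimetry import DEFAULT_WEIGHTS, recombine_benchmark
from bnctcheck.volio import read_volume, write_manifest, write_volume
from bnctcheck.workflow import ConfigError, RunConfig, run_head_plan, \
    run_plan_compare, run_water_qa


def _tiny_config(tmp_path, **kw):
    defaults = dict(
        voxel_size_mm=10.0, n_histories=3000, n_batches=3, seed=5,
        output_dir=str(tmp_path),
    )
    defaults.update(kw)
    return RunConfig(**defaults)


class TestRunConfig:
    def test_validation(self, tmp_path):
        with pytest.raises(ConfigError):
            RunConfig(voxel_size_mm=-1.0)
        with pytest.raises(ConfigError):
            RunConfig(n_histories=5, n_batches=10)

    def test_nonclinical_field_warns_but_runs(self, caplog):
        with caplog.at_level("WARNING", logger="bnctcheck"):
            RunConfig(field_diameters_cm=(8.0,))
        assert "clinical" in caplog.text


@pytest.fixture(scope="module")
def qa_result(tmp_path_factory):
    out = tmp_path_factory.mktemp("qa")
    config = RunConfig(
        voxel_size_mm=10.0, n_histories=3000, n_batches=3, seed=5,
        output_dir=str(out),
    )
    return config, run_water_qa(config), out


@pytest.fixture(scope="module")
def plan(tmp_path_factory):
    out = tmp_path_factory.mktemp("plan")
    config = RunConfig(
        voxel_size_mm=3.0, n_histories=4000, n_batches=4, seed=5,
        output_dir=str(out),
    )
    return run_head_plan(config)


class TestWaterQA:
    def test_one_profile_set_per_field(self, qa_result):
        config, result, _ = qa_result
        table = result["profiles"]
        assert set(table["field_cm"]) == set(config.field_diameters_cm)
        assert set(table["band"]) == {"thermal", "epithermal", "fast", "photon"}

    def test_manifest_records_seed_and_hash(self, qa_result):
        config, result, out = qa_result
        manifest = json.loads((out / "water_qa_manifest.json").read_text())
        assert manifest["seed"] == config.seed
        assert manifest["config_hash"] == result["manifest"]["config_hash"]
        assert "version" in manifest

    def test_csv_written(self, qa_result):
        _, _, out = qa_result
        table = pd.read_csv(out / "water_qa_profiles.csv")
        assert {"field_cm", "band", "axis", "position_mm",
                "flux_per_source"} <= set(table.columns)

    def test_larger_field_more_central_inscatter(self, tmp_path):
        """Per unit source fluence, the axial thermal flux at 6 cm depth
        does not fall when the field widens (geometric in-scatter)."""
        import bnctcheck as bc

        config = RunConfig(
            voxel_size_mm=10.0, n_histories=40_000, n_batches=10, seed=3,
            field_diameters_cm=(10.0, 15.0), output_dir=str(tmp_path),
        )
        result = run_water_qa(config)
        values = {}
        for diameter, tally in result["tallies"].items():
            prof = bc.depth_profile(tally, "thermal", axis=2)
            i = int(np.argmin(np.abs(prof["depth_mm"] - 60.0)))
            area = np.pi * (diameter / 2.0) ** 2
            values[diameter] = (
                prof["flux"][i] * area,
                prof["flux"][i] * np.nan_to_num(prof["relative_error"][i])
                * area,
            )
        small, e_small = values[10.0]
        big, e_big = values[15.0]
        assert big > small - 3.0 * np.hypot(e_small, e_big)


class TestHeadPlan:
    def test_report_covers_rois_and_components(self, plan):
        report = plan["report"]
        assert set(report["roi"]) == {"tumour", "brain", "skin"}
        assert set(report["component"]) == {
            "boron", "nitrogen", "hydrogen", "gamma", "weighted"
        }

    def test_zero_boron_removes_boron_dose(self, tmp_path):
        config = _tiny_config(tmp_path, voxel_size_mm=3.0,
                              boron_blood_ug_g=0.0, n_histories=2000,
                              n_batches=2)
        result = run_head_plan(config)
        report = result["report"]
        boron = report[report["component"] == "boron"]
        assert (boron["mean_gy"] == 0).all()
        # weighted dose then equals the RBE-weighted non-boron sum
        c = result["components"]
        w = DEFAULT_WEIGHTS["tumour"]
        tum = next(r for r in result["rois"] if r.name == "tumour").mask
        expected = (w.rbe_n * c.nitrogen + w.rbe_h * c.hydrogen
                    + w.rbe_gamma * c.gamma)[tum]
        assert np.allclose(result["weighted"][tum], expected)

    def test_benchmark_recombination_through_weighting_path(self):
        """The report's weighting path reproduces the published totals from
        the published component doses."""
        assert round(recombine_benchmark("brain", "neucure"), 1) == 4.5
        assert round(recombine_benchmark("tumour", "sera"), 1) == 67.9


class TestPlanCompare:
    def test_identical_inputs_full_pass(self):
        grid = bc.gen_depth_dose_fixture((12, 12, 16), 0.06, 8.0,
                                         spacing_mm=(3.0, 3.0, 3.0))
        result = run_plan_compare(grid, grid, [(3.0, 2.0), (1.0, 1.0)],
                                  spacing_mm=(3.0, 3.0, 3.0))
        assert all(r["pass_rate"] == 100.0 for r in result["rows"])
        assert len(result["rows"]) == 2

    def test_report_deterministic(self, tmp_path):
        grid = bc.gen_depth_dose_fixture((10, 10, 12), 0.06, 8.0)
        ev = bc.gen_perturbed_dose(grid, bc.PerturbationSpec(
            systematic_pct=2.0, noise_pct=1.0, seed=2))
        a = run_plan_compare(grid, ev, [(3.0, 2.0)],
                             output_dir=str(tmp_path / "a"))
        b = run_plan_compare(grid, ev, [(3.0, 2.0)],
                             output_dir=str(tmp_path / "b"))
        ja = (tmp_path / "a" / "gamma_report.json").read_bytes()
        jb = (tmp_path / "b" / "gamma_report.json").read_bytes()
        assert ja == jb

    def test_empty_criteria_rejected(self):
        with pytest.raises(ConfigError):
            run_plan_compare(np.ones((3, 3, 3)), np.ones((3, 3, 3)), [])


class TestVolumeIO:
    def test_volume_round_trip_bit_exact(self, tmp_path, rng):
        data = rng.random((7, 6, 5))
        path = write_volume(tmp_path / "vol.nii.gz", data,
                            voxel_size=(2.0, 2.0, 3.0), origin=(1.0, 0.0, -5.0))
        back, affine = read_volume(path)
        assert np.array_equal(back, data)
        assert np.allclose(np.diag(affine)[:3], (2.0, 2.0, 3.0))

    def test_manifest_round_trip(self, tmp_path):
        p = write_manifest(tmp_path / "m.json", {"a": 1}, seed=9)
        m = json.loads(p.read_text())
        assert m["seed"] == 9 and m["config"] == {"a": 1}


class TestCLI:
    def test_synth_and_gamma_commands(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "synth", "--shape", "10,10,12", "--systematic", "2.0",
            "--out", str(tmp_path),
        ])
        assert res.exit_code == 0, res.output
        res2 = runner.invoke(cli_main, [
            "gamma", str(tmp_path / "reference.nii.gz"),
            str(tmp_path / "evaluated.nii.gz"), "--criteria", "3/2",
        ])
        assert res2.exit_code == 0, res2.output
        rows = json.loads(res2.output)
        assert rows[0]["pass_rate"] == 100.0

    def test_foil_rate_command(self, tmp_path):
        counting = tmp_path / "counting.csv"
        history = tmp_path / "history.csv"
        lam = np.log(2) / (2.695 * 86400)
        counting.write_text(
            "segment_id,position_mm,counts,efficiency,emission_prob,"
            "lambda_per_s,t_cool_s,t_meas_s,mass_mg\n"
            f"s1,0.0,9000,0.02,0.956,{lam},3600,1800,2.0\n"
            f"s2,7.5,4000,0.02,0.956,{lam},3600,1800,2.0\n"
        )
        history.write_text("interval_s,charge_C\n900,0.15\n900,0.15\n")
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "foil-rate", str(counting), str(history), "--cadmium-pair",
        ])
        assert res.exit_code == 0, res.output
        assert "thermal_flux_per_C_cm2" in res.output
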