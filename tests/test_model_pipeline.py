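import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from mcpain import MCPredictionModel, compute_pain_scores
from mcpain.cli import main
from mcpain.config import validate_config
from mcpain.errors import InvalidParameterError
from mcpain.pipeline import run_pipeline, stage_seed


class TestMCPredictionModel:
    def test_from_cohort_nested_smoke(self, small_cohort, parc8):
        _, samples, pheno, truth = small_cohort
        model = MCPredictionModel.from_cohort(
            samples, pheno, parc8, feature_set="mc", threshold="laser", seed=5
        )
        res = model.fit()
        assert res.predictions.shape == (samples.n_participants,)
        assert np.isfinite(res.mae) and np.isfinite(res.pearson_r)
        txt = res.summary()
        assert "MAE" in txt and "nested" in txt

    def test_group_level_mode_reports_m_star(self, small_cohort, parc8):
        _, samples, pheno, _ = small_cohort
        model = MCPredictionModel.from_cohort(
            samples,
            pheno,
            parc8,
            feature_set="gmv",
            threshold="cold",
            mode="group_level",
            schedule=(1,),
        )
        res = model.fit()
        assert res.selection.m_star is not None
        assert len(res.selection.selected) == res.selection.m_star
        assert "m*" in res.summary()

    def test_score_threshold_uses_pain_score(self, small_cohort, parc8):
        _, samples, pheno, _ = small_cohort
        model = MCPredictionModel.from_cohort(
            samples, pheno, parc8, feature_set="gmv", threshold="score",
            mode="group_level", schedule=(1,),
        )
        scored = compute_pain_scores(pheno).set_index("participant_id")
        expected = scored.loc[list(samples.participants), "pain_sensitivity_score"]
        assert np.allclose(model.endog, expected.to_numpy())

    def test_gmv_mc_concatenation_width(self, small_cohort, parc8):
        _, samples, pheno, _ = small_cohort
        model = MCPredictionModel.from_cohort(
            samples, pheno, parc8, feature_set="gmv_mc", threshold="laser"
        )
        assert model.exog.shape[1] == 8 + 28

    def test_unknown_threshold_rejected(self, small_cohort, parc8):
        _, samples, pheno, _ = small_cohort
        with pytest.raises(InvalidParameterError):
            MCPredictionModel.from_cohort(samples, pheno, parc8, threshold="heat")


@pytest.fixture
def demo_config(tmp_path):
    cfg = {
        "simulation": {
            "n_participants": 16,
            "n_rois": 6,
            "n_voxels": 120,
            "n_planted_edges": 3,
            "target_r2": 0.8,
        },
        "feature_set": "mc",
        "threshold": "laser",
        "mode": "group_level",
        "schedule": [5, 1],
        "seed": 11,
        "out_dir": str(tmp_path / "out"),
    }
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return path


class TestConfig:
    def test_minimal_config_defaults(self, demo_config):
        cfg = validate_config(demo_config)
        assert cfg.mode == "group_level"
        assert cfg.inner_cv == 5

    def test_non_decreasing_schedule_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            yaml.safe_dump({"simulation": {}, "schedule": [10, 100]})
        )
        with pytest.raises(InvalidParameterError, match="strictly decreasing"):
            validate_config(path)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({"simulation": {}, "feature_sett": "mc"}))
        with pytest.raises(InvalidParameterError):
            validate_config(path)

    def test_bad_feature_set_lists_allowed_values(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({"simulation": {}, "feature_set": "mcc"}))
        with pytest.raises(InvalidParameterError, match="gmv_mc"):
            validate_config(path)

    def test_missing_inputs_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({"threshold": "laser"}))
        with pytest.raises(InvalidParameterError):
            validate_config(path)


class TestPipeline:
    def test_run_writes_report_and_manifest(self, demo_config):
        cfg = validate_config(demo_config)
        manifest = run_pipeline(cfg)
        out = cfg.out_dir
        report = json.load(open(f"{out}/report_mc_laser.json"))
        assert {"mae", "mrae", "pearson_r"} <= set(report)
        assert manifest["reports"]["mc_laser"]["n"] == 16
        assert (json.load(open(f"{out}/manifest.json"))["seed"]) == 11

    def test_rerun_is_bit_identical(self, demo_config, tmp_path):
        cfg = validate_config(demo_config)
        m1 = run_pipeline(cfg)
        cfg2 = cfg.model_copy(update={"out_dir": str(tmp_path / "out2")})
        m2 = run_pipeline(cfg2)
        assert m1["checksums"] == m2["checksums"]

    def test_stage_seed_distinct_and_bounded(self):
        seeds = {stage_seed(3, name) for name in ("simulate", "select:mc:laser", "x")}
        assert len(seeds) == 3
        assert all(0 <= s < 2**31 for s in seeds)


class TestCLI:
    def test_simulate_then_evaluate_roundtrip(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "cohort"
        r = runner.invoke(
            main,
            [
                "simulate", "--seed", "3", "--out", str(out),
                "--n-participants", "14", "--n-rois", "6",
                "--n-planted-edges", "2", "--target-r2", "0.8",
            ],
        )
        assert r.exit_code == 0, r.output
        assert (out / "roi_samples.tsv").exists()
        assert (out / "phenotypes.csv").exists()
        rep = tmp_path / "report.json"
        r = runner.invoke(
            main,
            [
                "evaluate",
                "--samples", str(out / "roi_samples.tsv"),
                "--phenotypes", str(out / "phenotypes.csv"),
                "--feature-set", "gmv", "--threshold", "laser",
                "--mode", "group_level", "--out", str(rep),
            ],
        )
        assert r.exit_code == 0, r.output
        report = json.loads(rep.read_text())
        assert "mae" in report and "selection" in report

    def test_run_command_with_config(self, demo_config):
        runner = CliRunner()
        r = runner.invoke(main, ["run", "--config", str(demo_config)])
        assert r.exit_code == 0, r.output
        assert "mc_laser" in r.output
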