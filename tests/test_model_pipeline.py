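import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import ratiopanel as rp
from ratiopanel.exceptions import ConfigError
from ratiopanel.pipeline import PipelineConfig, report_tables, run_pipeline


@pytest.fixture(scope="module")
def fitted(small_study_module):
    study = small_study_module
    model = rp.RatioPanelModel.from_matrices(
        study.training.ct,
        study.training.metadata,
        contrast="LAC+Benign vs. Control",
        annotations=study.annotations,
        counts=study.counts,
    )
    return study, model, model.fit(seed=7, max_rfe_features=30)


@pytest.fixture(scope="module")
def small_study_module():
    cfg = rp.SimulationConfig(
        n_species=40,
        n_per_group={"LAC": 18, "BENIGN": 14, "CONTROL": 14},
        n_per_group_validation={"LAC": 14, "BENIGN": 10, "CONTROL": 14},
        planted_pairs=(
            rp.PlantedPair(0, 1, 2.0, ("LAC", "BENIGN")),
            rp.PlantedPair(2, 3, 2.5, ("LAC",)),
        ),
        seed=42,
    )
    return rp.simulate_study(cfg)


class TestModel:
    def test_planted_pairs_among_candidates(self, fitted):
        study, _, res = fitted
        cand = set(res.candidates["pair_id"])
        assert study.truth.loc[0, "pair_id"] in cand  # affected in LAC+BENIGN

    def test_pair_stats_internal_consistency(self, fitted):
        _, _, res = fitted
        np.testing.assert_allclose(
            res.pair_stats["fold_change"], 2.0 ** res.pair_stats["ratio"], rtol=1e-12
        )
        assert (res.pair_stats["p_adjusted"] >= res.pair_stats["p_value"] - 1e-15).all()
        assert (res.candidates["auc"].between(0, 1)).all()

    def test_cv_auc_high_on_planted_structure(self, fitted):
        _, _, res = fitted
        assert res.panel is not None
        assert res.panel.cv_metrics.auc > 0.9

    def test_validation_evaluation(self, fitted):
        study, _, res = fitted
        vm = res.evaluate(study.validation.ct, study.validation.metadata)
        assert vm.auc > 0.8
        assert vm.tp + vm.fn == 24  # LAC + BENIGN arm of the validation cohort
        assert vm.tn + vm.fp == 14

    def test_summary_mentions_contrast_and_panel(self, fitted):
        _, _, res = fitted
        text = res.summary()
        assert "LAC+Benign vs. Control" in text
        assert "CV AUC" in text

    def test_panel_auc_single_code_path(self, fitted):
        """The panel AUC reported in metrics equals the auc() of the pooled
        CV decision values."""
        _, model, res = fitted
        direct = rp.auc(res.panel.cv_decision.to_numpy(), model.labels)
        assert res.panel.cv_metrics.auc == pytest.approx(direct, abs=1e-15)


def _run_cfg(seed=5):
    return PipelineConfig(
        simulate=rp.SimulationConfig(
            n_species=30,
            n_per_group={"LAC": 12, "BENIGN": 10, "CONTROL": 10},
            n_per_group_validation={"LAC": 10, "BENIGN": 8, "CONTROL": 10},
            planted_pairs=(rp.PlantedPair(0, 1, 2.0, ("LAC", "BENIGN")),),
            seed=seed,
        ),
        contrasts=["LAC+Benign vs. Control", "LAC vs. Control"],
        max_rfe_features=20,
        seed=seed,
    )


def _hashes(d: Path) -> dict:
    return {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(d.iterdir())
    }


class TestPipeline:
    def test_full_run_recovers_planted_pair(self, tmp_path):
        out = run_pipeline(_run_cfg(), tmp_path / "run")
        res = out["results"]["LAC+Benign vs. Control"]
        truth = out["inputs"]["truth"].loc[0, "pair_id"]
        assert truth in set(res.candidates["pair_id"])
        assert (tmp_path / "run" / "summary.txt").exists()
        assert (tmp_path / "run" / "panel_metrics.tsv").exists()

    def test_rerun_reports_byte_identical(self, tmp_path):
        run_pipeline(_run_cfg(), tmp_path / "a")
        run_pipeline(_run_cfg(), tmp_path / "b")
        assert _hashes(tmp_path / "a") == _hashes(tmp_path / "b")

    def test_zero_contrasts_rejected(self):
        with pytest.raises(ConfigError, match="contrast"):
            PipelineConfig(
                simulate=rp.SimulationConfig(n_species=5, planted_pairs=()),
                contrasts=[],
            )

    def test_file_inputs_required_without_simulation(self):
        with pytest.raises(ConfigError, match="simulate"):
            PipelineConfig()

    def test_report_rows_satisfy_rate_identities(self, tmp_path):
        run_pipeline(_run_cfg(), tmp_path / "run")
        table = pd.read_csv(tmp_path / "run" / "panel_metrics.tsv", sep="\t")
        np.testing.assert_allclose(table["fpr"] + table["spe"], 1.0, atol=1e-12)
        np.testing.assert_allclose(table["fnr"] + table["sen"], 1.0, atol=1e-12)

    def test_report_fc_matches_ratio_column(self, tmp_path):
        run_pipeline(_run_cfg(), tmp_path / "run")
        cand = pd.read_csv(
            tmp_path / "run" / "candidates_lac_benign_vs_control.tsv", sep="\t"
        )
        np.testing.assert_allclose(
            cand["fold_change"], 2.0 ** cand["ratio"], rtol=1e-12
        )

    def test_empty_candidate_report_still_valid(self, tmp_path):
        cfg = _run_cfg()
        cfg.fc_min = 1000.0  # nothing can pass
        run_pipeline(cfg, tmp_path / "run")
        cand = pd.read_csv(
            tmp_path / "run" / "candidates_lac_vs_control.tsv", sep="\t"
        )
        assert cand.empty
        assert list(cand.columns)[0] == "pair_id"

    def test_yaml_config_round_trip(self, tmp_path):
        import yaml

        doc = {
            "simulate": {
                "n_species": 12,
                "n_per_group": {"LAC": 8, "BENIGN": 6, "CONTROL": 6},
                "planted_pairs": [
                    {"species_a": 0, "species_b": 1, "effect_log2": 2.0}
                ],
                "seed": 3,
            },
            "contrasts": ["LAC vs. Control"],
            "seed": 3,
        }
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(doc))
        cfg = PipelineConfig.from_yaml(p)
        assert cfg.simulate.n_species == 12
        out = run_pipeline(cfg, tmp_path / "run")
        assert "LAC vs. Control" in out["results"]
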