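"""Model/Results interface, end-to-end orchestration, leakage audit, CLI."""

import dataclasses
import json

import numpy as np
import pytest

from restoselect import (
    ExperimentConfig,
    FeatureTable,
    RestorationModel,
    render_report,
    run_experiment,
)
from restoselect.exceptions import ConfigError
from restoselect.optimizer import HgwoPsoConfig, HgwoPsoResult, FitnessResult

FAST_OPT = HgwoPsoConfig(iterations=10)


def fast_config(seed=0):
    return ExperimentConfig(
        seed=seed,
        optimizer=FAST_OPT,
        bootstrap_B=50,
        enhance=None,  # features on raw phantom pixels
    )


class TestRestorationModel:
    def test_fit_summary_and_selection(self, phantom_features):
        res = RestorationModel(
            phantom_features, estimator="hgwo_pso_svm", optimizer=FAST_OPT
        ).fit(seed=0)
        assert 1 <= res.mask.sum() <= 25
        assert res.selection is not None
        text = res.summary()
        assert "hgwo_pso_svm" in text
        assert f"{int(res.mask.sum())} / 25" in text

    def test_plain_estimators_keep_all_features(self, phantom_features):
        for est in ("svm", "knn", "dt", "rf"):
            res = RestorationModel(phantom_features, estimator=est).fit(seed=0)
            assert res.mask.all()
            assert res.selection is None

    def test_unknown_estimator_rejected(self, phantom_features):
        with pytest.raises(ConfigError):
            RestorationModel(phantom_features, estimator="mlp")

    def test_predict_round_trip(self, phantom_features):
        res = RestorationModel(phantom_features, estimator="svm").fit(seed=0)
        preds = res.predict(phantom_features)
        assert preds.shape == phantom_features.y.shape
        assert set(preds) <= set(np.unique(phantom_features.y))

    def test_selection_disabled_reproduces_plain_svm(
        self, phantom_features, monkeypatch
    ):
        """An all-ones selection mask must reproduce the plain-SVM model
        exactly (identical predictions under the same seed)."""
        import restoselect.experiment as exp

        def all_ones_run(evaluator, d, cfg, callback=None):
            return HgwoPsoResult(
                mask=np.ones(d, dtype=bool),
                fitness=FitnessResult(1.0, 1.0, 0.9),
                history=[0.9],
                n_evaluations=1,
            )

        monkeypatch.setattr(exp, "run_hgwo_pso", all_ones_run)
        hybrid = RestorationModel(
            phantom_features, estimator="hgwo_pso_svm", optimizer=FAST_OPT
        ).fit(seed=3)
        plain = RestorationModel(phantom_features, estimator="svm").fit(seed=3)
        np.testing.assert_array_equal(
            hybrid.predict(phantom_features), plain.predict(phantom_features)
        )


@pytest.fixture(scope="module")
def report(phantom_features):
    return run_experiment(
        phantom_features, fast_config(seed=0), estimators=("svm", "hgwo_pso_svm")
    )


class TestRunExperiment:
    def test_report_structure(self, report):
        assert set(report["models"]) == {"svm", "hgwo_pso_svm"}
        for rep in report["models"].values():
            assert len(rep["fold_accuracies"]) == 5
            assert 0.0 <= rep["test"]["accuracy"] <= 1.0
            assert "ci" in rep["test"]
        assert report["models"]["hgwo_pso_svm"]["n_selected"] <= 25
        assert "paired_t_hgwo_vs_svm" in report

    def test_rerun_is_byte_identical(self, phantom_features, report):
        again = run_experiment(
            phantom_features, fast_config(seed=0), estimators=("svm", "hgwo_pso_svm")
        )
        assert json.dumps(report, sort_keys=True) == json.dumps(
            again, sort_keys=True
        )

    def test_leakage_audit_never_sees_test_rows(self, phantom_features):
        """No image id from the held-out patients may reach any
        standardizer fit, fitness evaluator, or grid search."""
        calls = []
        rep = run_experiment(
            phantom_features,
            fast_config(seed=1),
            estimators=("hgwo_pso_svm",),
            audit=lambda stage, ids: calls.append((stage, set(ids))),
        )
        test_patients = set(rep["split"]["test_patients"])
        test_ids = {
            i
            for i, p in zip(
                phantom_features.image_ids, phantom_features.patient_ids
            )
            if p in test_patients
        }
        assert calls, "audit hook was never invoked"
        stages = {s for s, _ in calls}
        assert {"standardizer_fit", "fitness_evaluator", "final_fit"} <= stages
        for stage, ids in calls:
            assert not (ids & test_ids), f"test rows leaked into {stage}"

    def test_render_matches_json_to_3_decimals(self, report):
        text = render_report(report)
        assert text.count("\n") > 5
        for est, rep in report["models"].items():
            assert est in text
            assert f"{rep['test']['macro_f1']:.3f}" in text

    def test_from_manifest_constructor(self, phantom_manifest):
        model = RestorationModel.from_manifest(
            phantom_manifest, estimator="dt"
        )
        res = model.fit(seed=0)
        assert res.mask.size == 25


class TestCli:
    def test_synth_features_select_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from restoselect.cli import main

        runner = CliRunner()
        data = tmp_path / "data"
        cfg = tmp_path / "spec.json"
        cfg.write_text(
            json.dumps(
                {"n_patients": 6, "images_per_patient": 3, "effect_size": 3.0}
            )
        )
        r = runner.invoke(
            main, ["synth", "--out", str(data), "--config", str(cfg), "--seed", "2"]
        )
        assert r.exit_code == 0, r.output
        assert (data / "manifest.csv").is_file()

        feats = tmp_path / "features.csv"
        r = runner.invoke(
            main,
            [
                "features",
                "--manifest",
                str(data / "manifest.csv"),
                "--out",
                str(feats),
                "--no-enhance",
            ],
        )
        assert r.exit_code == 0, r.output

        sel = tmp_path / "selection.json"
        opt_cfg = tmp_path / "opt.json"
        opt_cfg.write_text(json.dumps({"iterations": 5}))
        r = runner.invoke(
            main,
            [
                "select",
                "--features",
                str(feats),
                "--out",
                str(sel),
                "--config",
                str(opt_cfg),
                "--seed",
                "2",
            ],
        )
        assert r.exit_code == 0, r.output
        payload = json.loads(sel.read_text())
        assert len(payload["mask"]) == 25
        assert payload["fitness"]["F"] == pytest.approx(
            0.9 * payload["fitness"]["Acc"]
            + 0.1 * (1 - payload["fitness"]["Fr"]),
            abs=1e-12,
        )
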