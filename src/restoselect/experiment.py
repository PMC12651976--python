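"""Model/Results interface and the end-to-end benchmark experiment.

:class:`RestorationModel` is the user-facing estimator object: built
from a :class:`~restoselect.dataio.FeatureTable`, its :meth:`fit`
standardizes the feature columns, optionally runs HGWO-PSO wrapper
selection, trains the configured classifier, and returns a
:class:`RestorationResults` carrying the selected mask, optimizer
history and fitted pieces, with ``predict``/``evaluate``/``summary``.

:func:`run_experiment` reproduces the full benchmark protocol on a
manifest: patient-level 80/20 split, grouped 5-fold CV on the training
side with selection and tuning performed inside each fold, a final
model fitted on the whole training side, one assessment on the held-out
patients, stratified bootstrap CIs, and a paired t-test between the
hybrid and the plain-SVM arms.  Every stage seed derives
deterministically from the single experiment seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import models as _models
from .dataio import CLASSES, FEATURE_NAMES, FeatureTable, Manifest
from .evaluation import (
    bootstrap_ci,
    confusion,
    metrics,
    paired_t,
    patient_split,
)
from .exceptions import ConfigError
from .models import ClassifierConfig, FitnessEvaluator
from .optimizer import HgwoPsoConfig, HgwoPsoResult, run as run_hgwo_pso
from .preprocess import EnhanceConfig
from .texture import GlcmConfig, Standardizer, compute_feature_table

#: Estimator identifiers, in reporting order.
ESTIMATORS = ("knn", "svm", "dt", "rf", "hgwo_pso_svm")

#: Audit stages at which training-row image ids are reported.
AUDIT_STAGES = ("standardizer_fit", "fitness_evaluator", "grid_search", "final_fit")

AuditHook = Callable[[str, Sequence[str]], None]


def _derive_seed(*words: int) -> int:
    """Deterministic sub-seed (< 2**31) from integer words."""
    return int(np.random.SeedSequence(list(words)).generate_state(1)[0] % 2**31)


@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of the end-to-end experiment, under one global seed.

    The optimizer default here is the desk preset (30 iterations); pass
    ``HgwoPsoConfig()`` for the full 100-iteration setting.
    """

    enhance: EnhanceConfig | None = EnhanceConfig(crop_to=None)
    glcm: GlcmConfig = GlcmConfig()
    optimizer: HgwoPsoConfig = HgwoPsoConfig(iterations=30)
    classifiers: ClassifierConfig = ClassifierConfig()
    grid_search_svm: bool = True
    test_frac: float = 0.2
    k_folds: int = 5
    bootstrap_B: int = 1000
    bootstrap_level: float = 0.95
    seed: int = 0


class RestorationModel:
    """Texture-feature restoration classifier with optional HGWO-PSO selection.

    Parameters
    ----------
    table:
        Training feature table (all rows are treated as training data;
        outer splitting is the caller's concern — see
        :func:`run_experiment`).
    estimator:
        One of ``knn, svm, dt, rf, hgwo_pso_svm``.
    classifiers, optimizer:
        Hyperparameter bundles; optimizer settings are only consulted by
        the ``hgwo_pso_svm`` estimator.
    audit:
        Optional hook called as ``audit(stage, image_ids)`` whenever
        training rows enter a standardizer fit, fitness-evaluator
        construction, grid search or final fit — used to verify that
        held-out rows never leak into model building.
    """

    def __init__(
        self,
        table: FeatureTable,
        estimator: str = "hgwo_pso_svm",
        classifiers: ClassifierConfig | None = None,
        optimizer: HgwoPsoConfig | None = None,
        grid_search_svm: bool = False,
        audit: AuditHook | None = None,
    ) -> None:
        if estimator not in ESTIMATORS:
            raise ConfigError(f"estimator must be one of {ESTIMATORS}")
        self.table = table
        self.estimator = estimator
        self.classifiers = classifiers if classifiers is not None else ClassifierConfig()
        self.optimizer = optimizer if optimizer is not None else HgwoPsoConfig()
        self.grid_search_svm = grid_search_svm
        self.audit = audit

    @classmethod
    def from_dataframe(cls, frame, **kwargs) -> "RestorationModel":
        """Build from a raw DataFrame in the canonical feature schema."""
        return cls(FeatureTable(frame), **kwargs)

    @classmethod
    def from_manifest(
        cls,
        manifest: Manifest,
        glcm: GlcmConfig | None = None,
        enhance: EnhanceConfig | None = None,
        **kwargs,
    ) -> "RestorationModel":
        """Extract features from manifest images, then build the model."""
        return cls(compute_feature_table(manifest, glcm, enhance), **kwargs)

    def _audit(self, stage: str, ids: Sequence[str]) -> None:
        if self.audit is not None:
            self.audit(stage, list(ids))

    def fit(self, seed: int = 0) -> "RestorationResults":
        """Standardize, (optionally) select features, train the classifier."""
        table = self.table
        ids = list(table.image_ids)
        self._audit("standardizer_fit", ids)
        standardizer = Standardizer().fit(table.X, FEATURE_NAMES)
        Xs = standardizer.transform(table.X, FEATURE_NAMES)
        y = table.y

        selection: HgwoPsoResult | None = None
        if self.estimator == "hgwo_pso_svm":
            self._audit("fitness_evaluator", ids)
            evaluator = FitnessEvaluator(
                Xs,
                y,
                n_folds=self.classifiers.internal_cv_folds,
                svm=self.classifiers.svm,
                seed=seed,
            )
            opt_cfg = dataclasses.replace(self.optimizer, seed=seed)
            selection = run_hgwo_pso(evaluator, Xs.shape[1], opt_cfg)
            mask = selection.mask
        else:
            mask = np.ones(Xs.shape[1], dtype=bool)

        self._audit("final_fit", ids)
        if self.estimator in ("svm", "hgwo_pso_svm"):
            if self.grid_search_svm:
                self._audit("grid_search", ids)
            model = _models.train_svm(
                Xs[:, mask],
                y,
                self.classifiers.svm,
                seed=seed,
                grid_search=self.grid_search_svm,
                folds=self.classifiers.internal_cv_folds,
            )
        elif self.estimator == "knn":
            model = _models.train_knn(
                Xs[:, mask], y, self.classifiers.knn, seed=seed,
                folds=self.classifiers.internal_cv_folds,
            )
        elif self.estimator == "dt":
            model = _models.train_dt(Xs[:, mask], y, self.classifiers.dt, seed=seed)
        else:
            model = _models.train_rf(Xs[:, mask], y, self.classifiers.rf, seed=seed)

        return RestorationResults(
            model=self,
            classifier=model,
            standardizer=standardizer,
            mask=mask,
            selection=selection,
            seed=seed,
        )


@dataclasses.dataclass
class RestorationResults:
    """Fitted classifier plus selection outcome and evaluation helpers."""

    model: RestorationModel
    classifier: object
    standardizer: Standardizer
    mask: np.ndarray
    selection: HgwoPsoResult | None
    seed: int

    @property
    def selected_features(self) -> tuple[str, ...]:
        """Names of the feature columns the classifier consumes."""
        return tuple(np.asarray(FEATURE_NAMES)[self.mask])

    def predict(self, table: FeatureTable) -> np.ndarray:
        Xs = self.standardizer.transform(table.X, FEATURE_NAMES)
        return _models.predict(self.classifier, Xs[:, self.mask])

    def evaluate(
        self,
        table: FeatureTable,
        bootstrap_B: int = 0,
        level: float = 0.95,
        seed: int = 0,
    ) -> dict:
        """Confusion matrix + metric suite (and optional bootstrap CIs)."""
        y_pred = self.predict(table)
        cm = confusion(table.y, y_pred, CLASSES)
        report = metrics(cm, CLASSES)
        report["confusion"] = cm.tolist()
        report["n"] = int(len(table))
        if bootstrap_B:
            report["ci"] = bootstrap_ci(
                table.y, y_pred, B=bootstrap_B, level=level, seed=seed
            )
        return report

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        lines = [
            "RestorationModel fit summary",
            "============================",
            f"estimator          : {self.model.estimator}",
            f"training images    : {len(self.model.table)}",
            f"training patients  : {len(self.model.table.patients)}",
            f"seed               : {self.seed}",
            f"features selected  : {int(self.mask.sum())} / {self.mask.size}",
        ]
        if self.selection is not None:
            f = self.selection.fitness
            lines += [
                f"wrapper fitness F  : {f.fitness:.4f} "
                f"(Acc={f.acc:.4f}, Fr={f.frac_selected:.4f})",
                f"optimizer evals    : {self.selection.n_evaluations}",
                f"selected columns   : {', '.join(self.selected_features)}",
            ]
        return "\n".join(lines)


def run_experiment(
    source: Manifest | FeatureTable,
    cfg: ExperimentConfig | None = None,
    estimators: Sequence[str] = ESTIMATORS,
    audit: AuditHook | None = None,
) -> dict:
    """Run the full benchmark and return a JSON-serializable report.

    Per estimator: grouped k-fold CV on the training patients (feature
    standardization, selection and tuning are re-done inside every
    fold), then a final fit on the whole training side assessed once on
    the held-out patients with bootstrap CIs.
    """
    if cfg is None:
        cfg = ExperimentConfig()
    if isinstance(source, FeatureTable):
        table = source
    else:
        table = compute_feature_table(source, cfg.glcm, cfg.enhance)

    frame = table.frame
    records = Manifest(
        tuple(
            _record_stub(r.image_id, r.patient_id, r.label)
            for r in frame.itertuples(index=False)
        )
    )
    plan = patient_split(
        records, test_frac=cfg.test_frac, seed=_derive_seed(cfg.seed, 0), k=cfg.k_folds
    )
    train_table = table.subset_patients(plan.train_patients)
    test_table = table.subset_patients(plan.test_patients)

    report: dict = {
        "config": {
            "seed": cfg.seed,
            "test_frac": cfg.test_frac,
            "k_folds": cfg.k_folds,
            "bootstrap_B": cfg.bootstrap_B,
            "optimizer_iterations": cfg.optimizer.iterations,
            "n_wolves": cfg.optimizer.n_wolves,
        },
        "split": {
            "train_patients": list(plan.train_patients),
            "test_patients": list(plan.test_patients),
            "n_train_images": int(len(train_table)),
            "n_test_images": int(len(test_table)),
        },
        "models": {},
    }

    fold_acc: dict[str, list[float]] = {}
    for est_idx, est in enumerate(estimators):
        est_report: dict = {"fold_accuracies": [], "fold_masks": []}
        cv_true: list[str] = []
        cv_pred: list[str] = []
        for fold_idx, fold_patients in enumerate(plan.folds):
            fit_patients = [
                p for p in plan.train_patients if p not in set(fold_patients)
            ]
            fit_table = train_table.subset_patients(fit_patients)
            val_table = train_table.subset_patients(fold_patients)
            res = RestorationModel(
                fit_table,
                estimator=est,
                classifiers=cfg.classifiers,
                optimizer=cfg.optimizer,
                grid_search_svm=cfg.grid_search_svm and est in ("svm", "hgwo_pso_svm"),
                audit=audit,
            ).fit(seed=_derive_seed(cfg.seed, 1, est_idx, fold_idx))
            y_pred = res.predict(val_table)
            acc = float(np.mean(y_pred == val_table.y))
            est_report["fold_accuracies"].append(acc)
            est_report["fold_masks"].append(
                [int(v) for v in res.mask] if est == "hgwo_pso_svm" else None
            )
            cv_true.extend(val_table.y)
            cv_pred.extend(y_pred)

        fold_acc[est] = est_report["fold_accuracies"]
        est_report["cv_mean_accuracy"] = float(
            np.mean(est_report["fold_accuracies"])
        )
        est_report["cv_confusion"] = confusion(cv_true, cv_pred, CLASSES).tolist()

        final = RestorationModel(
            train_table,
            estimator=est,
            classifiers=cfg.classifiers,
            optimizer=cfg.optimizer,
            grid_search_svm=cfg.grid_search_svm and est in ("svm", "hgwo_pso_svm"),
            audit=audit,
        ).fit(seed=_derive_seed(cfg.seed, 2, est_idx))
        test_eval = final.evaluate(
            test_table,
            bootstrap_B=cfg.bootstrap_B,
            level=cfg.bootstrap_level,
            seed=_derive_seed(cfg.seed, 3, est_idx),
        )
        est_report["test"] = test_eval
        est_report["selected_features"] = list(final.selected_features)
        est_report["n_selected"] = int(final.mask.sum())
        if final.selection is not None:
            est_report["optimizer_history"] = [
                float(v) for v in final.selection.history
            ]
            est_report["wrapper_fitness"] = {
                "F": final.selection.fitness.fitness,
                "Acc": final.selection.fitness.acc,
                "Fr": final.selection.fitness.frac_selected,
            }
        report["models"][est] = est_report

    if "hgwo_pso_svm" in fold_acc and "svm" in fold_acc:
        t, p = paired_t(fold_acc["hgwo_pso_svm"], fold_acc["svm"])
        report["paired_t_hgwo_vs_svm"] = {"t": t, "p": p}
    return report


def _record_stub(image_id: str, patient_id: str, label: str):
    from .dataio import ImageRecord

    return ImageRecord(
        image_id=image_id, patient_id=patient_id, path=Path(""), label=label
    )


def render_report(report: dict) -> str:
    """Comparison table (model x Precision/Recall/F1/Accuracy) plus
    per-model confusion matrices, as plain text."""
    lines = [
        "Model comparison (held-out patient test set)",
        "--------------------------------------------",
        f"{'Model':<16}{'Precision':>10}{'Recall':>10}{'F1':>10}{'Accuracy':>12}",
    ]
    for est, rep in report["models"].items():
        t = rep["test"]
        lines.append(
            f"{est:<16}{t['macro_precision']:>10.3f}{t['macro_recall']:>10.3f}"
            f"{t['macro_f1']:>10.3f}{t['accuracy'] * 100:>11.2f}%"
        )
    lines.append("")
    for est, rep in report["models"].items():
        lines.append(f"Confusion matrix ({est}; rows=true, cols=pred; "
                     f"order {', '.join(CLASSES)}):")
        for row in rep["test"]["confusion"]:
            lines.append("  " + " ".join(f"{int(v):>4d}" for v in row))
        lines.append("")
    if "paired_t_hgwo_vs_svm" in report:
        tp = report["paired_t_hgwo_vs_svm"]
        lines.append(
            f"Paired t-test (HGWO-PSO+SVM vs SVM fold accuracies): "
            f"t={tp['t']:.3f}, p={tp['p']:.4f}"
        )
    return "\n".join(lines)


def save_report(report: dict, path: str | Path) -> Path:
    """Serialize a report to JSON deterministically (sorted keys)."""
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path
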