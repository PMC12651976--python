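"""Patient-level evaluation: splits, metrics, bootstrap CIs, agreement.

All data partitioning is done at the patient level so that every image
of a patient lands on the same side of any split — the leakage control
for repeated imaging of the same subject.  Metrics follow the usual
multi-class conventions: overall accuracy is trace/total of the
confusion matrix (equivalently the one-vs-rest (TP+TN)/(TP+TN+FP+FN)
micro form per class), per-class precision/recall/F1 use the 0/0 -> 0
convention, and macro metrics are unweighted means over the five
classes.  Uncertainty comes from a stratified bootstrap (resampling
within true-class strata) of the aggregated test predictions.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from .dataio import CLASSES, Manifest
from .exceptions import SplitError


@dataclasses.dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test patient sets plus k-fold assignments."""

    train_patients: tuple[str, ...]
    test_patients: tuple[str, ...]
    folds: tuple[tuple[str, ...], ...]  # CV folds partitioning train_patients
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_patients) & set(self.test_patients):
            raise SplitError("train and test patient sets overlap")
        fold_union: set[str] = set()
        for fold in self.folds:
            if fold_union & set(fold):
                raise SplitError("a patient appears in two CV folds")
            fold_union |= set(fold)
        if self.folds and fold_union != set(self.train_patients):
            raise SplitError("CV folds do not partition the training patients")


def _patient_image_counts(manifest: Manifest) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in manifest:
        counts[rec.patient_id] = counts.get(rec.patient_id, 0) + 1
    return counts


def _dominant_labels(manifest: Manifest) -> dict[str, str]:
    per_patient: dict[str, dict[str, int]] = {}
    for rec in manifest:
        per_patient.setdefault(rec.patient_id, {})
        per_patient[rec.patient_id][rec.label] = (
            per_patient[rec.patient_id].get(rec.label, 0) + 1
        )
    return {
        p: max(sorted(c), key=lambda lab: c[lab]) for p, c in per_patient.items()
    }


def patient_split(
    manifest: Manifest, test_frac: float = 0.2, seed: int = 0, k: int = 5
) -> SplitPlan:
    """80/20 patient-level split plus grouped k-fold plan on the train side.

    Patients are shuffled with the seed, interleaved across dominant
    labels (best-effort grouped stratification), and greedily assigned
    to the test side until its image count is as close as possible to
    ``test_frac`` of all images — never splitting a patient.
    """
    patients = list(manifest.patients)
    if len(patients) < 5:
        raise SplitError("need at least 5 patients for a patient-level split")
    rng = np.random.default_rng(seed)
    counts = _patient_image_counts(manifest)
    dominant = _dominant_labels(manifest)

    # Interleave label buckets so test picks cycle through classes.
    buckets: dict[str, list[str]] = {c: [] for c in CLASSES}
    for p in rng.permutation(patients):
        buckets[dominant[str(p)]].append(str(p))
    ordered: list[str] = []
    while any(buckets.values()):
        for c in CLASSES:
            if buckets[c]:
                ordered.append(buckets[c].pop())

    target = test_frac * len(manifest)
    test: list[str] = []
    n_test = 0
    for p in ordered:
        if abs(n_test + counts[p] - target) <= abs(n_test - target):
            test.append(p)
            n_test += counts[p]
        else:
            break
    if not test:
        test.append(ordered[0])
    train = [p for p in ordered if p not in set(test)]
    if not train:
        raise SplitError("test fraction leaves no training patients")
    folds = grouped_kfold(train, {p: counts[p] for p in train}, k=k, seed=seed)
    return SplitPlan(
        train_patients=tuple(train),
        test_patients=tuple(test),
        folds=folds,
        seed=seed,
    )


def grouped_kfold(
    patients: Sequence[str],
    image_counts: Mapping[str, int],
    k: int = 5,
    seed: int = 0,
) -> tuple[tuple[str, ...], ...]:
    """Partition patients into k folds of near-equal image counts.

    Greedy longest-processing-time assignment (largest patients first,
    ties shuffled by seed, each to the currently lightest fold), which
    bounds the fold-size spread by the largest per-patient image count.
    """
    if len(patients) < k:
        raise SplitError(f"cannot build {k} folds from {len(patients)} patients")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(list(patients)))
    order.sort(key=lambda p: -image_counts[str(p)])
    folds: list[list[str]] = [[] for _ in range(k)]
    loads = np.zeros(k)
    for p in order:
        # lightest fold; among ties, the fewest patients, then lowest index
        j = min(range(k), key=lambda i: (loads[i], len(folds[i]), i))
        folds[j].append(str(p))
        loads[j] += image_counts[str(p)]
    return tuple(tuple(f) for f in folds)


def confusion(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str] = CLASSES,
) -> np.ndarray:
    """Confusion matrix with rows = true class, cols = predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise SplitError("y_true and y_pred lengths differ")
    return confusion_matrix(y_true, y_pred, labels=list(classes))


def metrics(cm: np.ndarray, classes: Sequence[str] = CLASSES) -> dict:
    """Accuracy plus per-class and macro precision/recall/F1 from a matrix.

    0/0 ratios are defined as 0; macro averages always run over all
    listed classes, including those absent from the data.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise SplitError("empty confusion matrix")
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / pr, 0.0)
    return {
        "accuracy": float(tp.sum() / total),
        "per_class": {
            c: {
                "precision": float(precision[i]),
                "recall": float(recall[i]),
                "f1": float(f1[i]),
            }
            for i, c in enumerate(classes)
        },
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
    }


def bootstrap_ci(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    classes: Sequence[str] = CLASSES,
) -> dict:
    """Stratified bootstrap percentile CIs for accuracy and macro metrics.

    Indices are resampled with replacement within each true-class
    stratum; strata with zero instances are skipped with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size < 10:
        raise SplitError("bootstrap requires at least 10 predictions")
    rng = np.random.default_rng(seed)
    strata = []
    for c in classes:
        idx = np.flatnonzero(y_true == c)
        if idx.size == 0:
            warnings.warn(f"class {c!r} has no instances; stratum skipped")
        else:
            strata.append(idx)
    stats_names = ("accuracy", "macro_precision", "macro_recall", "macro_f1")
    reps = np.empty((B, len(stats_names)))
    for b in range(B):
        take = np.concatenate(
            [rng.choice(idx, size=idx.size, replace=True) for idx in strata]
        )
        m = metrics(confusion(y_true[take], y_pred[take], classes), classes)
        reps[b] = [m[s] for s in stats_names]
    lo = (1 - level) / 2 * 100
    hi = 100 - lo
    return {
        name: {
            "lower": float(np.percentile(reps[:, j], lo)),
            "upper": float(np.percentile(reps[:, j], hi)),
        }
        for j, name in enumerate(stats_names)
    }


def paired_t(acc_a: Sequence[float], acc_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on fold-level accuracies.

    Zero-variance differences: all-zero differences give (0.0, 1.0); a
    constant nonzero difference gives t = +-inf with p = 0.0 and a
    warning, by convention.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise SplitError("paired t-test needs two equal-length vectors, n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero differences; reporting t = +-inf")
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def cohen_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Chance-corrected inter-rater agreement (po - pe) / (1 - pe).

    When both raters produce the same constant labeling, pe = 1 and
    kappa is defined as 1 with a warning.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.size == 0:
        raise SplitError("label vectors must be equal-length and nonempty")
    if np.unique(a).size == 1 and np.unique(b).size == 1 and a[0] == b[0]:
        warnings.warn("both raters constant and equal; kappa defined as 1")
        return 1.0
    return float(cohen_kappa_score(a, b))
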