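"""Patient-level splitting, metric arithmetic, bootstrap, agreement."""

import numpy as np
import pytest
from pathlib import Path
from scipy import stats

from restoselect import (
    CLASSES,
    ImageRecord,
    Manifest,
    bootstrap_ci,
    cohen_kappa,
    confusion,
    grouped_kfold,
    metrics,
    paired_t,
    patient_split,
)
from restoselect.exceptions import SplitError


def _manifest(patient_sizes, labels=None, seed=0):
    """Manifest stub with given per-patient image counts."""
    rng = np.random.default_rng(seed)
    records = []
    k = 0
    for i, n in enumerate(patient_sizes):
        for _ in range(n):
            lab = labels[i] if labels else CLASSES[int(rng.integers(5))]
            records.append(
                ImageRecord(f"im{k}", f"p{i}", Path(""), lab)
            )
            k += 1
    return Manifest(tuple(records))


class TestPatientSplit:
    def test_ten_patients_two_images_each(self):
        man = _manifest([2] * 10)
        plan = patient_split(man, test_frac=0.2, seed=0)
        assert len(plan.test_patients) == 2
        assert not set(plan.train_patients) & set(plan.test_patients)
        assert set(plan.train_patients) | set(plan.test_patients) == set(
            man.patients
        )

    def test_patient_atomicity_over_random_manifests(self):
        rng = np.random.default_rng(1)
        for trial in range(20):
            sizes = rng.integers(1, 6, size=rng.integers(6, 15))
            man = _manifest(list(sizes), seed=trial)
            plan = patient_split(man, seed=trial, k=min(5, len(sizes) - 1))
            sides = {p: "train" for p in plan.train_patients}
            sides.update({p: "test" for p in plan.test_patients})
            for rec in man:
                assert rec.patient_id in sides

    def test_deterministic(self):
        man = _manifest([3] * 12)
        a = patient_split(man, seed=5)
        b = patient_split(man, seed=5)
        assert a == b

    def test_too_few_patients_rejected(self):
        with pytest.raises(SplitError):
            patient_split(_manifest([2] * 4), k=2)


class TestGroupedKfold:
    def test_25_equal_patients_five_folds_of_five(self):
        patients = [f"p{i}" for i in range(25)]
        folds = grouped_kfold(patients, {p: 2 for p in patients}, k=5, seed=0)
        assert len(folds) == 5
        assert all(len(f) == 5 for f in folds)

    def test_folds_partition_patients(self):
        patients = [f"p{i}" for i in range(13)]
        counts = {p: int(np.random.default_rng(i).integers(1, 5)) for i, p in enumerate(patients)}
        folds = grouped_kfold(patients, counts, k=4, seed=1)
        seen = [p for f in folds for p in f]
        assert sorted(seen) == sorted(patients)

    def test_balance_bound(self):
        rng = np.random.default_rng(2)
        patients = [f"p{i}" for i in range(20)]
        counts = {p: int(rng.integers(1, 8)) for p in patients}
        folds = grouped_kfold(patients, counts, k=5, seed=2)
        loads = [sum(counts[p] for p in f) for f in folds]
        assert max(loads) - min(loads) <= max(counts.values())

    def test_too_few_patients_rejected(self):
        with pytest.raises(SplitError):
            grouped_kfold(["a", "b"], {"a": 1, "b": 1}, k=3)


class TestConfusionAndMetrics:
    def test_perfect_predictions_diagonal(self):
        y = np.array(["crown", "filling", "implant", "crown"])
        cm = confusion(y, y)
        assert cm.sum() == 4
        assert np.all(cm == np.diag(np.diag(cm)))
        rep = metrics(cm)
        assert rep["accuracy"] == 1.0
        # classes present score 1; absent classes use the 0/0 -> 0 rule
        assert rep["per_class"]["crown"]["f1"] == 1.0
        assert rep["per_class"]["bridge"]["f1"] == 0.0

    def test_single_offdiagonal_cell(self):
        cm = confusion(["crown"] * 3, ["bridge"] * 3)
        i, j = CLASSES.index("crown"), CLASSES.index("bridge")
        assert cm[i, j] == 3 and cm.sum() == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(SplitError):
            confusion(["crown"], ["crown", "bridge"])

    def test_two_class_hand_arithmetic(self):
        """[[50,10],[5,35]] embedded in the 5-class matrix."""
        cm = np.zeros((5, 5))
        cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1] = 50, 10, 5, 35
        rep = metrics(cm)
        assert rep["accuracy"] == pytest.approx(0.85, abs=1e-12)
        c0 = rep["per_class"][CLASSES[0]]
        assert c0["precision"] == pytest.approx(50 / 55, abs=1e-12)
        assert c0["recall"] == pytest.approx(50 / 60, abs=1e-12)

    def test_macro_invariant_under_class_permutation(self):
        rng = np.random.default_rng(3)
        y_true = rng.choice(CLASSES, 60)
        y_pred = rng.choice(CLASSES, 60)
        rep = metrics(confusion(y_true, y_pred, CLASSES))
        perm = tuple(reversed(CLASSES))
        rep_p = metrics(confusion(y_true, y_pred, perm), perm)
        assert rep["macro_f1"] == pytest.approx(rep_p["macro_f1"], abs=1e-12)

    def test_metrics_of_self_confusion_all_ones(self):
        y = np.array(["implant", "crown", "implant", "root_canal"])
        rep = metrics(confusion(y, y))
        assert rep["accuracy"] == 1.0
        for c in np.unique(y):
            assert rep["per_class"][c]["precision"] == 1.0
            assert rep["per_class"][c]["recall"] == 1.0


class TestBootstrap:
    def _predictions(self, n, err, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.choice(CLASSES, n)
        y_pred = y_true.copy()
        flip = rng.random(n) < err
        y_pred[flip] = rng.choice(CLASSES, flip.sum())
        return y_true, y_pred

    def test_all_correct_degenerate_ci(self):
        y = np.array(["crown", "filling", "implant", "bridge", "root_canal"] * 4)
        ci = bootstrap_ci(y, y, B=50, seed=0)
        assert ci["accuracy"] == {"lower": 1.0, "upper": 1.0}
        assert ci["macro_f1"]["lower"] == 1.0

    def test_point_estimate_inside_ci(self):
        for seed in range(5):
            y_true, y_pred = self._predictions(80, 0.3, seed)
            acc = metrics(confusion(y_true, y_pred))["accuracy"]
            ci = bootstrap_ci(y_true, y_pred, B=400, seed=seed)
            assert ci["accuracy"]["lower"] - 1e-9 <= acc <= ci["accuracy"]["upper"] + 1e-9

    def test_ci_width_shrinks_with_n(self):
        widths = {50: [], 500: []}
        for seed in range(20):
            for n in (50, 500):
                y_true, y_pred = self._predictions(n, 0.3, 100 + seed)
                ci = bootstrap_ci(y_true, y_pred, B=200, seed=seed)["accuracy"]
                widths[n].append(ci["upper"] - ci["lower"])
        assert np.mean(widths[500]) < np.mean(widths[50])

    def test_empty_stratum_warns(self):
        y_true = np.array(["crown"] * 10)  # four classes absent
        with pytest.warns(UserWarning):
            bootstrap_ci(y_true, y_true, B=20, seed=0)


class TestPairedT:
    def test_identical_vectors_convention(self):
        assert paired_t([0.7, 0.8, 0.6], [0.7, 0.8, 0.6]) == (0.0, 1.0)

    def test_constant_nonzero_difference_branch(self):
        with pytest.warns(UserWarning):
            t, p = paired_t([0.8] * 5, [0.7] * 5)
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_scipy_on_generic_input(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(8), rng.random(8)
        t, p = paired_t(a, b)
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(float(t_ref)) and p == pytest.approx(float(p_ref))

    def test_bad_shapes_rejected(self):
        with pytest.raises(SplitError):
            paired_t([0.5], [0.5])


class TestCohenKappa:
    def test_identical_nonconstant_is_one(self):
        labels = np.array(["crown", "bridge", "crown", "implant"])
        assert cohen_kappa(labels, labels) == 1.0

    def test_hand_worked_agreement_table(self):
        """Counts [[20,5],[10,15]] -> po=0.7, pe=0.5, kappa=0.4."""
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        assert cohen_kappa(a, b) == pytest.approx(0.4, abs=1e-12)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.choice(["x", "y"], 10000)
        b = rng.choice(["x", "y"], 10000)
        assert abs(cohen_kappa(a, b)) < 0.05

    def test_both_constant_equal_defined_as_one(self):
        with pytest.warns(UserWarning):
            assert cohen_kappa(["x"] * 5, ["x"] * 5) == 1.0
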