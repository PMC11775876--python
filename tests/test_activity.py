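"""Hierarchical activity recognition: gate, posture model, conv net, scoring."""
import numpy as np
import pandas as pd
import pytest

from ahrkit import RunConfig
from ahrkit.activity import (
    evaluate_activity,
    loso_predict,
    train_dynamic_model,
    train_gate,
    tune_posture_model,
)
from ahrkit.config import POSTURE_SEARCH_SPACE
from ahrkit.core import ALL_CLASSES, EpochSet
from ahrkit.errors import (
    ConfigurationError,
    DegenerateTrainingError,
    InsufficientCohortError,
)


def gate_features(n_static=60, n_dynamic=60, seed=0):
    """Separable-by-construction fixture: dynamic epochs have large VM SD."""
    rng = np.random.default_rng(seed)
    vm_sd = np.concatenate(
        [rng.normal(0.001, 0.0002, n_static), rng.normal(0.3, 0.05, n_dynamic)]
    )
    feats = pd.DataFrame(
        {
            "vm_std": vm_sd,
            "noise1": rng.normal(size=n_static + n_dynamic),
            "noise2": rng.normal(size=n_static + n_dynamic),
        }
    )
    labels = np.array(["static"] * n_static + ["dynamic"] * n_dynamic, dtype=object)
    return feats, labels


class TestGate:
    def test_separable_fixture_held_out_accuracy(self):
        feats, labels = gate_features(seed=1)
        model, cost = train_gate(feats, labels, seed=0)
        test_f, test_l = gate_features(seed=2)
        acc = (model.predict(test_f.to_numpy()) == test_l).mean()
        assert acc >= 0.99

    def test_chosen_cost_within_stated_range(self):
        feats, labels = gate_features(seed=3)
        _, cost = train_gate(feats, labels, seed=0)
        assert 2 <= cost <= 16

    def test_deterministic_under_fixed_seed(self):
        feats, labels = gate_features(seed=4)
        _, c1 = train_gate(feats, labels, seed=5)
        _, c2 = train_gate(feats, labels, seed=5)
        assert c1 == c2

    def test_single_class_rejected(self):
        feats, labels = gate_features(n_dynamic=0)
        with pytest.raises(DegenerateTrainingError):
            train_gate(feats, labels)


def posture_features(n_per_class=50, seed=0):
    """Posture separable through the mean vertical (gravity) component."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    means = {"lying": 0.0, "sitting": -0.8, "standing": -1.0}
    for cls, m in means.items():
        for _ in range(n_per_class):
            rows.append(
                {
                    "y_mean": m + rng.normal(0, 0.03),
                    "x_mean": rng.normal(0, 0.1),
                    "noise": rng.normal(),
                }
            )
            labels.append(cls)
    return pd.DataFrame(rows), np.array(labels, dtype=object)


class TestPostureModel:
    def test_search_budget_is_ten_per_hyperparameter(self):
        cfg = RunConfig()
        assert len(cfg.boosted_tree_search_space) == 8
        assert cfg.tpe_budget == 80

    def test_separable_fixture_and_params_in_range(self):
        tr_f, tr_l = posture_features(seed=0)
        va_f, va_l = posture_features(n_per_class=15, seed=1)
        model, params = tune_posture_model(tr_f, tr_l, va_f, va_l, seed=2)
        for name, (lo, hi) in POSTURE_SEARCH_SPACE.items():
            assert lo <= params[name] <= hi
        te_f, te_l = posture_features(n_per_class=20, seed=3)
        classes = model._ahrkit_classes
        pred = np.array([classes[c] for c in model.predict(te_f.to_numpy())])
        assert (pred == te_l).mean() >= 0.95

    def test_empty_validation_split_rejected(self):
        tr_f, tr_l = posture_features(n_per_class=5)
        with pytest.raises(ConfigurationError):
            tune_posture_model(tr_f, tr_l, tr_f.iloc[:0], tr_l[:0])


def dynamic_epochs(n_per_class=24, seed=0, fs=100.0, samples=600):
    """Class-specific dominant frequencies/amplitudes (separable fixture)."""
    kin = {
        "walking": (2.0, 0.4), "jogging": (3.0, 0.9),
        "cycling": (1.5, 0.15), "stairs": (2.0, 0.6),
    }
    rng = np.random.default_rng(seed)
    t = np.arange(samples) / fs
    X, labels = [], []
    for cls, (f, a) in kin.items():
        for _ in range(n_per_class):
            xyz = rng.normal(0, 0.05, size=(samples, 3))
            xyz[:, 1] += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            xyz[:, 0] += 0.5 * a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            if cls == "stairs":
                xyz[:, 1] += rng.normal(0, 0.3, size=samples)
            X.append(xyz)
            labels.append(cls)
    return np.array(X), np.array(labels, dtype=object)


class TestDynamicModel:
    @pytest.fixture(scope="class")
    def trained(self):
        X, y = dynamic_epochs(seed=0)
        return train_dynamic_model(X, y, seed=0), X, y

    def test_separable_fixture_held_out_accuracy(self, trained):
        model, _, _ = trained
        Xte, yte = dynamic_epochs(n_per_class=10, seed=9)
        assert (model.predict(Xte) == yte).mean() >= 0.90

    def test_training_loss_decreases_on_average(self, trained):
        model, _, _ = trained
        hist = np.asarray(model.net.loss_history, dtype=float)
        assert np.mean(hist[-10:]) < np.mean(hist[:10])

    def test_same_seed_identical_predictions(self, trained):
        model, X, y = trained
        model2 = train_dynamic_model(X, y, seed=0)
        Xte, _ = dynamic_epochs(n_per_class=5, seed=4)
        np.testing.assert_array_equal(model.predict(Xte), model2.predict(Xte))

    def test_missing_class_warns(self):
        X, y = dynamic_epochs(n_per_class=8, seed=2)
        keep = y != "stairs"
        with pytest.warns(UserWarning, match="stairs"):
            train_dynamic_model(X[keep], y[keep], seed=0,
                                config=RunConfig(conv_iterations=2))


def tiny_epoch_sets(n_subjects=4, seed=0):
    """Cohort of per-subject EpochSets mixing postures and dynamic classes."""
    sets = []
    for i in range(n_subjects):
        Xd, yd = dynamic_epochs(n_per_class=6, seed=seed + i)
        rng = np.random.default_rng(seed + 100 + i)
        n_static = 36
        Xs = rng.normal(0, 0.005, size=(n_static, 600, 3))
        ys = []
        means = {"lying": (-1, 0), "sitting": (0.57, -0.82), "standing": (0, -1)}
        for j in range(n_static):
            cls = list(means)[j % 3]
            Xs[j, :, 0] += means[cls][0]
            Xs[j, :, 1] += means[cls][1]
            ys.append(cls)
        X = np.concatenate([Xs, Xd])
        y = np.concatenate([np.array(ys, dtype=object), yd])
        vm = np.linalg.norm(X - X.mean(axis=1, keepdims=True), axis=2)
        sets.append(
            EpochSet(subject=f"s{i}", start_s=np.arange(len(X)) * 3.0, x=X,
                     vm=vm, label_true=y)
        )
    return sets


class TestLOSO:
    def test_insufficient_cohort_rejected(self):
        with pytest.raises(InsufficientCohortError):
            loso_predict(tiny_epoch_sets(n_subjects=2))

    def test_every_subject_gets_aligned_predictions(self):
        sets = tiny_epoch_sets(n_subjects=4)
        cfg = RunConfig(conv_iterations=10)
        preds = loso_predict(sets, config=cfg, seed=0)
        assert set(preds) == {f"s{i}" for i in range(4)}
        for es in sets:
            assert len(preds[es.subject]) == es.n_epochs
            assert set(preds[es.subject]) <= set(ALL_CLASSES)


class TestEvaluateActivity:
    def test_perfect_predictions(self):
        y = np.array(list(ALL_CLASSES) * 4, dtype=object)
        subj = np.array(["a"] * 14 + ["b"] * 14)
        rep = evaluate_activity(y, y, subj)
        assert rep.summary["accuracy_mean"] == 1.0
        assert rep.summary["f1_weighted_mean"] == 1.0
        np.testing.assert_allclose(np.diag(rep.confusion), 1.0)

    def test_constant_prediction_on_balanced_subject(self):
        y = np.array(list(ALL_CLASSES) * 3, dtype=object)
        pred = np.full(len(y), "sitting", dtype=object)
        rep = evaluate_activity(y, pred, np.full(len(y), "a"))
        assert rep.summary["accuracy_mean"] == pytest.approx(1 / 7)

    def test_weighted_f1_matches_brute_force(self):
        rng = np.random.default_rng(5)
        y = rng.choice(ALL_CLASSES[:4], size=60)
        pred = rng.choice(ALL_CLASSES[:4], size=60)
        rep = evaluate_activity(y, pred, np.full(60, "a"))
        # brute force: per-class F1 weighted by true support
        total = 0.0
        for cls in set(y):
            tp = np.sum((y == cls) & (pred == cls))
            fp = np.sum((y != cls) & (pred == cls))
            fn = np.sum((y == cls) & (pred != cls))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            total += f1 * np.sum(y == cls)
        assert rep.summary["f1_weighted_mean"] == pytest.approx(total / len(y))

    def test_confusion_rows_normalised_or_flagged(self):
        y = np.array(["lying", "sitting", "sitting"], dtype=object)
        rep = evaluate_activity(y, y, np.full(3, "a"))
        sums = rep.confusion.sum(axis=1)
        for cls in ALL_CLASSES:
            if cls in ("lying", "sitting"):
                assert sums[cls] == pytest.approx(1.0, abs=1e-9)
            else:
                assert sums[cls] == 0.0
                assert cls in rep.zero_support_rows

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            evaluate_activity(np.array([]), np.array([]), np.array([]))
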