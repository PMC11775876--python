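"""Hierarchical activity recognition under leave-one-subject-out CV.

Three stages: a linear SVM separates static from dynamic epochs; static
epochs go to a gradient-boosted-tree posture classifier (hyperparameters
chosen by a Bayesian TPE search, budget 10 evaluations per hyperparameter);
dynamic epochs go to a small convolutional classifier over the raw epoch
samples. Training and tuning never see the held-out subject: the remaining
subjects are split 90%/10% at the subject level into a training and a
validation set.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_score,
    recall_score,
    f1_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .bayesopt import tpe_minimize
from .config import INTEGER_PARAMS, RunConfig
from .convnet import ConvNetClassifier
from .core import ALL_CLASSES, DYNAMIC_CLASSES, STATIC_CLASSES, UNKNOWN, EpochSet
from .errors import (
    ConfigurationError,
    DegenerateTrainingError,
    InsufficientCohortError,
)
from .features import extract_features, standardize_features, apply_scaler


def train_gate(
    features: pd.DataFrame,
    labels: np.ndarray,
    cost_range: tuple[float, float] = (2, 16),
    seed: int = 0,
) -> tuple[SVC, float]:
    """Linear SVM separating static from dynamic epochs.

    The cost hyperparameter is chosen from an integer grid over
    ``cost_range`` by 5-fold cross-validated accuracy; ties go to the
    smaller cost. ``labels`` must be the binary static/dynamic labels.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise DegenerateTrainingError("gate training requires both classes")
    costs = np.arange(int(cost_range[0]), int(cost_range[1]) + 1)
    X = features.to_numpy()
    n_splits = min(5, np.bincount(pd.factorize(labels)[0]).min())
    best_cost, best_acc = None, -1.0
    if n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = list(cv.split(X, labels))
        for c in costs:
            accs = []
            for tr, te in splits:
                m = SVC(kernel="linear", C=float(c)).fit(X[tr], labels[tr])
                accs.append(accuracy_score(labels[te], m.predict(X[te])))
            acc = float(np.mean(accs))
            if acc > best_acc + 1e-12:
                best_acc, best_cost = acc, float(c)
    else:
        best_cost = float(costs[0])
    model = SVC(kernel="linear", C=best_cost).fit(X, labels)
    return model, best_cost


def _make_xgb(params: dict, n_classes: int, seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=50,
        max_depth=int(params["max_depth"]),
        gamma=params["gamma"],
        learning_rate=params["eta"],
        reg_alpha=params["reg_alpha"],
        reg_lambda=params["reg_lambda"],
        subsample=params["subsample"],
        colsample_bytree=params["colsample_bytree"],
        min_child_weight=params["min_child_weight"],
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )


def tune_posture_model(
    train_X: pd.DataFrame,
    train_y: np.ndarray,
    val_X: pd.DataFrame,
    val_y: np.ndarray,
    config: RunConfig | None = None,
    seed: int = 0,
) -> tuple[XGBClassifier, dict]:
    """Boosted-tree posture classifier with TPE-searched hyperparameters.

    The search budget is 10 evaluations per ordinal hyperparameter (80 for
    the default 8-dimensional space); the objective is weighted F1 on the
    held-out validation split.
    """
    cfg = config or RunConfig()
    if len(val_X) == 0 or len(val_y) == 0:
        raise ConfigurationError("empty validation split for posture tuning")
    space = cfg.boosted_tree_search_space
    classes = [c for c in STATIC_CLASSES]
    cls_idx = {c: i for i, c in enumerate(classes)}
    ytr = np.array([cls_idx[c] for c in train_y])
    yva = np.array([cls_idx[c] for c in val_y])
    Xtr, Xva = train_X.to_numpy(), val_X.to_numpy()

    def objective(params: dict) -> float:
        m = _make_xgb(params, len(classes), seed)
        m.fit(Xtr, ytr)
        pred = m.predict(Xva)
        return -f1_score(yva, pred, average="weighted", zero_division=0)

    rng = np.random.default_rng(seed)
    best_params, _, _ = tpe_minimize(
        objective, space, n_evals=cfg.tpe_budget, rng=rng,
        integer_params=INTEGER_PARAMS,
    )
    model = _make_xgb(best_params, len(classes), seed)
    model.fit(Xtr, ytr)
    model._ahrkit_classes = classes  # type: ignore[attr-defined]
    return model, best_params


@dataclass
class DynamicModel:
    """Conv net plus the per-channel training statistics it was fit with."""

    net: ConvNetClassifier
    chan_mean: np.ndarray
    chan_sd: np.ndarray

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        sd = np.where(self.chan_sd > 0, self.chan_sd, 1.0)
        return (X - self.chan_mean) / sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict(self._standardize(X))


def train_dynamic_model(
    X: np.ndarray, labels: np.ndarray, config: RunConfig | None = None, seed: int = 0
) -> DynamicModel:
    """Train the convolutional activity-type classifier on raw epochs.

    ``X`` has shape (n_epochs, samples, 3); channels are standardised with
    training statistics before entering the network.
    """
    cfg = config or RunConfig()
    chan_mean = X.mean(axis=(0, 1))
    chan_sd = X.std(axis=(0, 1))
    net = ConvNetClassifier(
        classes=list(DYNAMIC_CLASSES),
        lr=cfg.conv_lr,
        decay=cfg.conv_decay,
        momentum=cfg.conv_nesterov_momentum,
        max_epochs=cfg.conv_iterations,
        seed=seed,
    )
    model = DynamicModel(net=net, chan_mean=chan_mean, chan_sd=chan_sd)
    net.fit(model._standardize(np.asarray(X, dtype=float)), labels)
    return model


@dataclass
class ActivityModelBundle:
    """All three classifiers plus the feature scaler of one LOSO fold."""

    gate: SVC
    gate_cost: float
    posture_model: XGBClassifier
    posture_params: dict
    dynamic_model: DynamicModel
    scaler: dict
    classes: tuple[str, ...] = ALL_CLASSES

    def predict(self, features: pd.DataFrame, raw_x: np.ndarray) -> np.ndarray:
        """Hierarchical per-epoch prediction: gate, then posture or type."""
        feats_std = apply_scaler(features, self.scaler)
        gate_pred = self.gate.predict(feats_std.to_numpy())
        out = np.empty(len(features), dtype=object)
        static_sel = gate_pred == "static"
        if static_sel.any():
            codes = self.posture_model.predict(feats_std.to_numpy()[static_sel])
            classes = self.posture_model._ahrkit_classes
            out[static_sel] = [classes[c] for c in codes]
        if (~static_sel).any():
            out[~static_sel] = self.dynamic_model.predict(raw_x[~static_sel])
        return out


def _gate_labels(labels: np.ndarray) -> np.ndarray:
    return np.where(np.isin(labels, STATIC_CLASSES), "static", "dynamic")


def train_bundle(
    train_feats: pd.DataFrame,
    train_labels: np.ndarray,
    train_x: np.ndarray,
    val_feats: pd.DataFrame,
    val_labels: np.ndarray,
    config: RunConfig | None = None,
    seed: int = 0,
) -> ActivityModelBundle:
    """Fit gate, posture and dynamic models on one train/validation split."""
    cfg = config or RunConfig()
    feats_std, scaler = standardize_features(train_feats)
    gate, cost = train_gate(
        feats_std, _gate_labels(train_labels), cfg.svm_cost_range, seed=seed
    )
    static_tr = np.isin(train_labels, STATIC_CLASSES)
    static_va = np.isin(val_labels, STATIC_CLASSES)
    posture, pparams = tune_posture_model(
        feats_std[static_tr],
        train_labels[static_tr],
        apply_scaler(val_feats[static_va], scaler),
        val_labels[static_va],
        config=cfg,
        seed=seed,
    )
    dyn_sel = ~static_tr
    dynamic = train_dynamic_model(
        train_x[dyn_sel], train_labels[dyn_sel], config=cfg, seed=seed
    )
    return ActivityModelBundle(
        gate=gate,
        gate_cost=cost,
        posture_model=posture,
        posture_params=pparams,
        dynamic_model=dynamic,
        scaler=scaler,
    )


def loso_predict(
    epoch_sets: list[EpochSet],
    config: RunConfig | None = None,
    seed: int = 0,
    return_bundles: bool = False,
):
    """Leave-one-subject-out predictions for every subject's epochs.

    For each held-out subject the remaining subjects are split 90/10 at the
    subject level (seeded); models are trained on the training subjects and
    tuned on the validation subjects; the held-out subject contributes no
    training or tuning data. Returns ``{subject: predicted labels}`` (epoch
    order preserved) and optionally the per-fold model bundles.
    """
    cfg = config or RunConfig()
    if len(epoch_sets) < 3:
        raise InsufficientCohortError("LOSO requires at least 3 subjects")
    subjects = [es.subject for es in epoch_sets]
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids")
    feats = {es.subject: extract_features(es) for es in epoch_sets}
    by_subject = {es.subject: es for es in epoch_sets}

    seeds = np.random.SeedSequence(seed).generate_state(2 * len(subjects)) % (2**31)
    predictions: dict[str, np.ndarray] = {}
    bundles: dict[str, ActivityModelBundle] = {}
    for i, held_out in enumerate(subjects):
        rng = np.random.default_rng(int(seeds[2 * i]))
        others = [s for s in subjects if s != held_out]
        order = rng.permutation(len(others))
        n_val = max(1, int(round(0.1 * len(others))))
        val_subjects = {others[j] for j in order[:n_val]}
        train_subjects = [s for s in others if s not in val_subjects]

        def _stack(subs):
            f = pd.concat([feats[s] for s in subs], ignore_index=True)
            lab = np.concatenate([by_subject[s].label_true for s in subs])
            x = np.concatenate([by_subject[s].x for s in subs])
            known = lab != UNKNOWN
            return f[known].reset_index(drop=True), lab[known], x[known]

        tr_f, tr_l, tr_x = _stack(train_subjects)
        va_f, va_l, _ = _stack(sorted(val_subjects))
        bundle = train_bundle(
            tr_f, tr_l, tr_x, va_f, va_l, config=cfg, seed=int(seeds[2 * i + 1])
        )
        es = by_subject[held_out]
        predictions[held_out] = bundle.predict(feats[held_out], es.x)
        es.label_pred = predictions[held_out]
        if return_bundles:
            bundles[held_out] = bundle
    if return_bundles:
        return predictions, bundles
    return predictions


@dataclass
class ClassificationReport:
    """Per-subject weighted metrics plus an occurrence-normalised confusion matrix."""

    per_subject: pd.DataFrame
    summary: dict = field(default_factory=dict)
    confusion: pd.DataFrame | None = None
    zero_support_rows: list[str] = field(default_factory=list)


def evaluate_activity(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    subjects: np.ndarray,
    classes: tuple[str, ...] = ALL_CLASSES,
) -> ClassificationReport:
    """Score aligned prediction/truth labels grouped by subject.

    Weighted precision/recall/F1 use true-class support within each subject
    as weights; the cohort summary reports mean +/- SD across subjects. The
    confusion matrix is pooled over subjects and row-normalised by
    true-class occurrence (zero-support rows stay all-zero and are flagged).
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    subjects = np.asarray(subjects)
    if len(y_true) == 0:
        raise ValueError("empty predictions")
    known = np.isin(y_true, classes)
    y_true, y_pred, subjects = y_true[known], y_pred[known], subjects[known]

    rows = []
    for s in pd.unique(subjects):
        sel = subjects == s
        yt, yp = y_true[sel], y_pred[sel]
        rows.append(
            {
                "subject": s,
                "accuracy": accuracy_score(yt, yp),
                "f1_weighted": f1_score(yt, yp, average="weighted", zero_division=0),
                "precision_weighted": precision_score(
                    yt, yp, average="weighted", zero_division=0
                ),
                "recall_weighted": recall_score(
                    yt, yp, average="weighted", zero_division=0
                ),
            }
        )
    per_subject = pd.DataFrame(rows)
    summary = {}
    for m in ("accuracy", "f1_weighted", "precision_weighted", "recall_weighted"):
        summary[f"{m}_mean"] = float(per_subject[m].mean())
        summary[f"{m}_sd"] = float(per_subject[m].std(ddof=1)) if len(per_subject) > 1 else 0.0

    labels = list(classes)
    cm = confusion_matrix(y_true, y_pred, labels=labels).astype(float)
    support = cm.sum(axis=1)
    zero_rows = [labels[i] for i in range(len(labels)) if support[i] == 0]
    norm = cm / np.where(support[:, None] > 0, support[:, None], 1.0)
    confusion = pd.DataFrame(norm, index=labels, columns=labels)
    return ClassificationReport(
        per_subject=per_subject,
        summary=summary,
        confusion=confusion,
        zero_support_rows=zero_rows,
    )
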