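"""Per-subject regression of heart rate on movement covariates.

Four nested ordinary-least-squares models predict the 30-s mean heart rate
(pHR, beats per minute):

  Model 1: pHR ~ 1 + VM
  Model 2: pHR ~ 1 + VM + posture (sitting, standing; lying reference)
  Model 3: pHR ~ 1 + VM + activity class (6 dummies; lying reference)
  Model 4: Model 3 + lagged VM (mean VM of the 6 preceding windows)

In Model 2 every window contributes its underlying posture (locomotion is
upright, ergometer cycling seated). Each subject is fitted with seeded
5-fold cross-validation: 80% of windows fit the model, the held-out 20%
receive predictions, so no window is predicted by a model that saw it.
Model quality is summarised by adjusted R^2 and RMSE on the held-out
predictions with stress windows excluded, and consecutive models are
compared across subjects with paired t-tests at alpha = 0.05/2.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import RunConfig
from .core import ALL_CLASSES, POSTURE_OF, UNKNOWN
from .errors import DataError, InsufficientCohortError, UndefinedMetricError

logger = logging.getLogger(__name__)

#: Nominal covariate count (excluding the intercept) per model.
NOMINAL_P = {1: 1, 2: 3, 3: 7, 4: 8}

_MIN_WINDOWS = 30


def build_design(
    windows: pd.DataFrame, model_id: int, label_col: str = "activity_pred"
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Response and covariate table for one model.

    Returns (y, X, kept_windows). Windows lacking a valid heart rate, with
    an unknown activity label, or (Model 4 only) without a full lag history
    are dropped; unknown-label drops are logged.
    """
    if model_id not in NOMINAL_P:
        raise ValueError(f"model_id must be 1..4, got {model_id}")
    keep = windows["hr_valid"].astype(bool).to_numpy()
    labels = windows[label_col].astype(object).to_numpy()
    unknown = ~np.isin(labels, ALL_CLASSES)
    if model_id >= 2:
        n_drop = int((keep & unknown).sum())
        if n_drop:
            logger.info("dropping %d windows with unknown activity label", n_drop)
        keep &= ~unknown
    if model_id == 4:
        keep &= windows["lag_valid"].astype(bool).to_numpy()
    kept = windows[keep].copy()
    labels = kept[label_col].astype(object).to_numpy()

    X = pd.DataFrame({"const": np.ones(len(kept))}, index=kept.index)
    X["vm"] = kept["mean_vm_g"].to_numpy()
    if model_id == 2:
        posture = np.array([POSTURE_OF.get(l, UNKNOWN) for l in labels])
        for p in ("sitting", "standing"):
            X[p] = (posture == p).astype(float)
    elif model_id >= 3:
        for cls in ALL_CLASSES[1:]:  # lying is the reference
            X[cls] = (labels == cls).astype(float)
    if model_id == 4:
        X["lag_vm"] = kept["lag_vm_g"].to_numpy()
    y = kept["mean_hr_bpm"].astype(float)
    return y, X, kept


@dataclass
class HRModelFit:
    """Cross-validated fit of one model for one subject."""

    subject: str
    model_id: int
    coef: pd.Series  # mean over folds
    coef_folds: pd.DataFrame  # one row per fold, NaN where a dummy was dropped
    coef_full: pd.Series  # refit on all usable windows
    adj_r2: float = np.nan
    rmse_bpm: float = np.nan
    n_windows: int = 0
    dropped_dummies: list = field(default_factory=list)


def _ols_fit_predict(
    y_tr: pd.Series, X_tr: pd.DataFrame, X_te: pd.DataFrame
) -> tuple[pd.Series, np.ndarray, list[str]]:
    """OLS with per-fold dropping of zero-variance dummy columns."""
    dummy_cols = [c for c in X_tr.columns if c not in ("const", "vm", "lag_vm")]
    drop = [c for c in dummy_cols if X_tr[c].nunique() == 1]
    remaining = [c for c in dummy_cols if c not in drop]
    # if the reference class is absent from the fold, the remaining dummies
    # sum to the intercept; fold the first one into the reference
    if remaining and (X_tr[remaining].sum(axis=1) == 1.0).all():
        drop.append(remaining[0])
    if drop:
        logger.info("fold dropped rank-deficient dummies: %s", drop)
    cols = [c for c in X_tr.columns if c not in drop]
    res = sm.OLS(y_tr.to_numpy(), X_tr[cols].to_numpy()).fit()
    coefs = pd.Series(res.params, index=cols)
    pred = X_te[cols].to_numpy() @ res.params
    return coefs, pred, drop


def fit_predict_cv(
    windows: pd.DataFrame,
    model_id: int,
    k: int = 5,
    config: RunConfig | None = None,
    seed: int = 0,
    label_col: str = "activity_pred",
) -> tuple[pd.DataFrame, HRModelFit]:
    """Held-out pHR for every usable window of one subject.

    Windows are assigned to ``k`` seeded random folds; each window's pHR
    comes from the fold that excluded it. Reported coefficients are the
    fold means; a full-data refit is stored alongside.
    """
    subject = str(windows["subject"].iloc[0]) if len(windows) else "?"
    y, X, kept = build_design(windows, model_id, label_col=label_col)
    n = len(y)
    if n < _MIN_WINDOWS:
        raise DataError(
            f"subject {subject}: only {n} usable windows (< {_MIN_WINDOWS}) "
            f"for model {model_id}"
        )
    rng = np.random.default_rng(seed)
    fold_of = np.asarray([i % k for i in range(n)])
    rng.shuffle(fold_of)

    phr = np.full(n, np.nan)
    fold_rows, dropped_all = [], []
    for f in range(k):
        te = fold_of == f
        coefs, pred, dropped = _ols_fit_predict(y[~te], X[~te], X[te])
        phr[te] = pred
        fold_rows.append(coefs)
        dropped_all.extend(d for d in dropped if d not in dropped_all)
    coef_folds = pd.DataFrame(fold_rows).reindex(columns=X.columns)
    coef_full, _, _ = _ols_fit_predict(y, X, X.iloc[:0])
    fit = HRModelFit(
        subject=subject,
        model_id=model_id,
        coef=coef_folds.mean(axis=0, skipna=True),
        coef_folds=coef_folds,
        coef_full=coef_full.reindex(X.columns),
        n_windows=n,
        dropped_dummies=dropped_all,
    )
    out = kept.copy()
    out["phr_bpm"] = phr
    return out, fit


def model_metrics(
    ohr: np.ndarray,
    phr: np.ndarray,
    model_id: int,
    stress_mask: np.ndarray,
) -> tuple[float, float]:
    """Adjusted R^2 and RMSE (BPM) on non-stress held-out windows.

    adj R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1), with p the nominal
    covariate count of the model (the adjustment uses the nominal p because
    the predictions are out-of-sample).
    """
    ohr, phr = np.asarray(ohr, float), np.asarray(phr, float)
    keep = ~np.asarray(stress_mask, bool)
    ohr, phr = ohr[keep], phr[keep]
    p = NOMINAL_P[model_id]
    n = len(ohr)
    if n <= p + 1:
        raise UndefinedMetricError(f"n={n} too small for p={p}")
    ss_res = float(np.sum((ohr - phr) ** 2))
    ss_tot = float(np.sum((ohr - ohr.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    rmse = float(np.sqrt(ss_res / n))
    return adj, rmse


def fit_subject_all_models(
    windows: pd.DataFrame,
    config: RunConfig | None = None,
    seed: int = 0,
    label_col: str = "activity_pred",
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Fit Models 1-4 for one subject; returns per-model windows and metrics."""
    per_model, rows = {}, []
    for m in (1, 2, 3, 4):
        out, fit = fit_predict_cv(
            windows, m, config=config, seed=seed, label_col=label_col
        )
        adj, rmse = model_metrics(
            out["mean_hr_bpm"].to_numpy(),
            out["phr_bpm"].to_numpy(),
            m,
            out["is_stress"].to_numpy(dtype=bool),
        )
        fit.adj_r2, fit.rmse_bpm = adj, rmse
        per_model[m] = out
        rows.append(
            {
                "subject": fit.subject,
                "model_id": m,
                "adj_r2": adj,
                "rmse_bpm": rmse,
                "fit": fit,
            }
        )
    return per_model, pd.DataFrame(rows)


@dataclass
class ModelComparison:
    """Paired t-tests on per-subject metrics for consecutive model pairs."""

    table: pd.DataFrame  # columns: pair, metric, mean_a, mean_b, t, df, p, significant
    alpha: float


def compare_models(
    metrics: pd.DataFrame, alpha: float = 0.025
) -> ModelComparison:
    """Compare models 2v1, 3v2, 4v3 on adjusted R^2 and RMSE across subjects.

    ``metrics`` needs columns subject, model_id, adj_r2, rmse_bpm with the
    same subjects present for all four models. Two-sided p-values; df is
    n_subjects - 1.
    """
    wide = {
        m: metrics[metrics["model_id"] == m].set_index("subject").sort_index()
        for m in (1, 2, 3, 4)
    }
    n = len(wide[1])
    if n < 3:
        raise InsufficientCohortError("model comparison requires >= 3 subjects")
    for m in (2, 3, 4):
        if not wide[m].index.equals(wide[1].index):
            raise DataError("same subjects required for all four models")
    rows = []
    for a, b in ((2, 1), (3, 2), (4, 3)):
        for metric in ("adj_r2", "rmse_bpm"):
            xa = wide[a][metric].to_numpy()
            xb = wide[b][metric].to_numpy()
            if np.allclose(xa, xb):
                t, pval = 0.0, 1.0
            else:
                t, pval = stats.ttest_rel(xa, xb)
            rows.append(
                {
                    "pair": f"{a}v{b}",
                    "metric": metric,
                    "mean_new": float(xa.mean()),
                    "mean_old": float(xb.mean()),
                    "t": float(t),
                    "df": n - 1,
                    "p": float(pval),
                    "significant": bool(pval < alpha),
                }
            )
    return ModelComparison(table=pd.DataFrame(rows), alpha=alpha)
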