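"""Additional heart rate (aHR), classic reactivity (dHR) and their validation.

aHR is the residual of the movement-based prediction, aHR = oHR - pHR: the
part of heart rate that movement covariates cannot explain, read as a
mental-stress signal. Classic reactivity dHR subtracts a posture-matched
baseline condition mean instead (sitting baseline for seated stress tasks,
standing baseline for locomotion). The two validation analyses mirror the
method's design: between subjects, per-condition correlation of subject
mean aHR with subject mean dHR; within subjects, the top fraction
(default 30%) of a subject's aHR observations is declared "stress" and
scored against the scheduled stress conditions, in parallel with the same
rule applied to raw oHR.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import POSTURE_OF, ProtocolEvent
from .errors import AlignmentError

logger = logging.getLogger(__name__)


def compute_ahr(windows: pd.DataFrame) -> pd.DataFrame:
    """Append ``ahr_bpm = mean_hr_bpm - phr_bpm`` to a window table."""
    if "phr_bpm" not in windows.columns:
        raise AlignmentError("windows carry no pHR column; fit an HR model first")
    out = windows.copy()
    out["ahr_bpm"] = out["mean_hr_bpm"] - out["phr_bpm"]
    return out


def _baseline_hr_by_posture(
    grp: pd.DataFrame, schedule: list[ProtocolEvent]
) -> dict[str, float]:
    """Mean HR of the baseline condition(s) per posture, for one subject.

    Where a posture has several baseline conditions, the reference is the
    average of the per-condition means.
    """
    cond_means: dict[str, list[float]] = {}
    for i, ev in enumerate(schedule):
        if not ev.is_baseline:
            continue
        sel = (grp["condition_idx"] == i) & grp["hr_valid"]
        if sel.any():
            posture = POSTURE_OF.get(ev.activity_class, ev.activity_class)
            cond_means.setdefault(posture, []).append(
                float(grp.loc[sel, "mean_hr_bpm"].mean())
            )
    return {p: float(np.mean(v)) for p, v in cond_means.items()}


def compute_delta_hr(
    windows: pd.DataFrame, schedule: list[ProtocolEvent]
) -> pd.DataFrame:
    """Classic HR reactivity per window, with posture-specific baselines.

    Windows inside a condition get oHR minus the baseline mean of the
    condition's reference posture. Windows in between-condition gaps get
    oHR minus the mean HR of their own gap period; they are flagged
    ``visualization_only`` and excluded from summary analyses.
    """
    out = windows.copy()
    out["delta_hr_bpm"] = np.nan
    out["visualization_only"] = False
    for subject, grp in out.groupby("subject", sort=False):
        base = _baseline_hr_by_posture(grp, schedule)
        for i, ev in enumerate(schedule):
            sel = (out["subject"] == subject) & (out["condition_idx"] == i)
            if not sel.any():
                continue
            posture = POSTURE_OF.get(ev.activity_class, ev.activity_class)
            if posture in base:
                out.loc[sel, "delta_hr_bpm"] = (
                    out.loc[sel, "mean_hr_bpm"] - base[posture]
                )
            else:
                logger.info(
                    "subject %s: no %s baseline for condition %r",
                    subject, posture, ev.label,
                )
        # gap periods: contiguous runs of windows outside any condition
        gap = (out["subject"] == subject) & (out["condition_idx"] < 0)
        if gap.any():
            idx = out.index[gap]
            widx = out.loc[idx, "window_idx"].to_numpy()
            period = np.concatenate([[0], np.cumsum(np.diff(widx) > 1)])
            for p in np.unique(period):
                pidx = idx[period == p]
                valid = out.loc[pidx, "hr_valid"].to_numpy(dtype=bool)
                if valid.any():
                    mean_hr = float(out.loc[pidx[valid], "mean_hr_bpm"].mean())
                    out.loc[pidx, "delta_hr_bpm"] = (
                        out.loc[pidx, "mean_hr_bpm"] - mean_hr
                    )
            out.loc[idx, "visualization_only"] = True
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def condition_summary(
    windows: pd.DataFrame, schedule: list[ProtocolEvent]
) -> pd.DataFrame:
    """Per-condition cohort table of dHR and aHR (means, SDs, correlation).

    One row per scheduled condition occurrence: number of subjects with
    data, mean +/- SD across subjects of the subject-level dHR and aHR
    means, and the Pearson r between the subject-level dHR and aHR means
    (undefined below 3 subjects or at zero variance).
    """
    viz = (
        windows["visualization_only"].astype(bool)
        if "visualization_only" in windows.columns
        else pd.Series(False, index=windows.index)
    )
    analysable = windows[
        windows["hr_valid"] & (windows["condition_idx"] >= 0) & ~viz
    ]
    rows = []
    for i, ev in enumerate(schedule):
        sub = analysable[analysable["condition_idx"] == i]
        per_subj = sub.groupby("subject")[["delta_hr_bpm", "ahr_bpm"]].mean().dropna()
        n = len(per_subj)
        d, a = per_subj["delta_hr_bpm"].to_numpy(), per_subj["ahr_bpm"].to_numpy()
        rows.append(
            {
                "condition_idx": i,
                "condition": ev.label,
                "is_stress": ev.is_stress,
                "n": n,
                "delta_hr_mean": float(d.mean()) if n else np.nan,
                "delta_hr_sd": float(d.std(ddof=1)) if n > 1 else np.nan,
                "ahr_mean": float(a.mean()) if n else np.nan,
                "ahr_sd": float(a.std(ddof=1)) if n > 1 else np.nan,
                "r": _pearson(d, a),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ScatterData:
    """Per-subject (mean aHR, mean dHR) pairs for one stress condition."""

    condition: str
    points: pd.DataFrame  # columns: subject, ahr_mean, delta_hr_mean
    r: float
    centroid: tuple[float, float]


def between_subject_scatter(
    windows: pd.DataFrame, schedule: list[ProtocolEvent], condition_idx: int
) -> ScatterData:
    """Scatter of subject-mean aHR (x) against subject-mean dHR (y)."""
    ev = schedule[condition_idx]
    sub = windows[
        windows["hr_valid"] & (windows["condition_idx"] == condition_idx)
    ]
    pts = (
        sub.groupby("subject")[["ahr_bpm", "delta_hr_bpm"]]
        .mean()
        .dropna()
        .rename(columns={"ahr_bpm": "ahr_mean", "delta_hr_bpm": "delta_hr_mean"})
        .reset_index()
    )
    x, y = pts["ahr_mean"].to_numpy(), pts["delta_hr_mean"].to_numpy()
    centroid = (float(x.mean()), float(y.mean())) if len(pts) else (np.nan, np.nan)
    return ScatterData(
        condition=ev.label, points=pts, r=_pearson(x, y), centroid=centroid
    )


@dataclass
class StressDetectionReport:
    """Within-subject top-fraction stress detection, per subject and cohort."""

    signal: str
    threshold_fraction: float
    per_subject: pd.DataFrame  # subject, n, n_stress, recall, precision, f1
    mean_confusion: pd.DataFrame  # rows true {stress, non_stress}, normalised
    sd_confusion: pd.DataFrame
    summary: dict = field(default_factory=dict)
    excluded_subjects: list = field(default_factory=list)


def within_subject_detection(
    windows: pd.DataFrame,
    threshold_fraction: float = 0.30,
    signal: str = "ahr",
) -> StressDetectionReport:
    """Declare each subject's top-fraction windows "stress" and score them.

    ``signal`` selects aHR (``"ahr"``) or raw observed HR (``"ohr"``). Only
    valid windows inside experimental conditions count; the scheduled
    stress flag is the ground truth. Ties at the threshold are broken by
    including earlier windows first. Confusion matrices are row-normalised
    by true-class occurrence; subjects without any stress window are
    excluded from the stress-class metric averaging and logged.
    """
    col = {"ahr": "ahr_bpm", "ohr": "mean_hr_bpm"}[signal]
    usable = windows[
        windows["hr_valid"]
        & (windows["condition_idx"] >= 0)
        & windows[col].notna()
    ]
    rows, confusions, excluded = [], {}, []
    for subject, grp in usable.groupby("subject", sort=False):
        grp = grp.sort_values("window_idx", kind="mergesort")
        grp = grp.sort_values(col, ascending=False, kind="mergesort")
        n = len(grp)
        k = int(round(threshold_fraction * n))
        pred_stress = np.zeros(n, dtype=bool)
        pred_stress[:k] = True
        true_stress = grp["is_stress"].to_numpy(dtype=bool)

        tp = int((pred_stress & true_stress).sum())
        fn = int((~pred_stress & true_stress).sum())
        fp = int((pred_stress & ~true_stress).sum())
        tn = int((~pred_stress & ~true_stress).sum())
        n_stress = tp + fn
        n_non = fp + tn
        cm = np.full((2, 2), np.nan)
        if n_stress > 0:
            cm[0] = [tp / n_stress, fn / n_stress]
        if n_non > 0:
            cm[1] = [fp / n_non, tn / n_non]
        confusions[subject] = cm
        if n_stress == 0:
            excluded.append(subject)
            logger.info("subject %s has no stress windows; excluded from recall", subject)
            continue
        recall = tp / n_stress
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        rows.append(
            {
                "subject": subject,
                "n": n,
                "n_stress": n_stress,
                "recall": recall,
                "precision": precision,
                "f1": f1,
            }
        )
    per_subject = pd.DataFrame(
        rows, columns=["subject", "n", "n_stress", "recall", "precision", "f1"]
    )
    stack = np.array(list(confusions.values()))
    with np.errstate(invalid="ignore"):
        mean_cm = np.nanmean(stack, axis=0) if len(stack) else np.full((2, 2), np.nan)
        sd_cm = np.nanstd(stack, axis=0, ddof=1) if len(stack) > 1 else np.zeros((2, 2))
    labels = ["stress", "non_stress"]
    cols = ["pred_stress", "pred_non_stress"]
    summary = {}
    for m in ("recall", "precision", "f1"):
        vals = per_subject[m].to_numpy(dtype=float)
        summary[f"{m}_mean"] = float(vals.mean()) if len(vals) else np.nan
        summary[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return StressDetectionReport(
        signal=signal,
        threshold_fraction=threshold_fraction,
        per_subject=per_subject,
        mean_confusion=pd.DataFrame(mean_cm, index=labels, columns=cols),
        sd_confusion=pd.DataFrame(sd_cm, index=labels, columns=cols),
        summary=summary,
        excluded_subjects=excluded,
    )
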