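"""Signal conditioning, vector magnitude, epoching and windowing.

The conditioning chain is: 4th-order 5-Hz low-pass Butterworth, then IIR
antialiasing decimation from the raw rate (nominally 1000 Hz) to 100 Hz.
For the vector magnitude (VM) only, a 4th-order 0.1-Hz high-pass is applied
to a copy of the raw signals first, removing the gravity component. All
filters run zero-phase (forward-backward), so the VM and heart-rate series
stay time-aligned.

Segmentation: 6-s epochs overlapping by 50% (starts at 0, 3, 6, ... s) feed
the activity classifiers; non-overlapping 30-s windows carry the analysis
quantities. Each window aggregates the ten epochs whose start time falls
inside it, and the majority-voted epoch label becomes the window label.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .config import RunConfig
from .core import (
    ALL_CLASSES,
    UNKNOWN,
    BeatSeries,
    EpochSet,
    ProtocolEvent,
    TriaxialRecording,
)
from .errors import TooShortError

TARGET_FS = 100.0
_LOWPASS_HZ = 5.0
_HIGHPASS_HZ = 0.1


def _filtfilt_axes(rec: TriaxialRecording, sos: np.ndarray) -> TriaxialRecording:
    out = rec.copy()
    out.ax = signal.sosfiltfilt(sos, rec.ax)
    out.ay = signal.sosfiltfilt(sos, rec.ay)
    out.az = signal.sosfiltfilt(sos, rec.az)
    return out


def condition_signal(raw: TriaxialRecording) -> TriaxialRecording:
    """Low-pass filter and decimate a raw recording to 100 Hz."""
    if raw.duration_s < 1.0:
        raise TooShortError("recording shorter than 1 s cannot be conditioned")
    sos = signal.butter(4, _LOWPASS_HZ, btype="low", fs=raw.fs, output="sos")
    filtered = _filtfilt_axes(raw, sos)
    q = int(round(raw.fs / TARGET_FS))
    if q > 1:
        # IIR antialiasing at 0.8x the new Nyquist, zero phase. Butterworth
        # (maximally flat) keeps the passband -- notably DC, i.e. gravity --
        # at exactly unit gain, unlike a rippled Chebyshev design.
        aa = signal.butter(8, 0.8 * (raw.fs / q) / 2, fs=raw.fs, output="sos")
        ax = signal.sosfiltfilt(aa, filtered.ax)[::q]
        ay = signal.sosfiltfilt(aa, filtered.ay)[::q]
        az = signal.sosfiltfilt(aa, filtered.az)[::q]
    else:
        ax, ay, az = filtered.ax, filtered.ay, filtered.az
    return TriaxialRecording(ax=ax, ay=ay, az=az, fs=raw.fs / q if q > 1 else raw.fs,
                             gravity_corrected=raw.gravity_corrected)


def gravity_correct(raw: TriaxialRecording) -> TriaxialRecording:
    """High-pass (0.1 Hz) a copy of the raw signals, then condition as usual.

    The output is used only for the VM; per-axis classification features keep
    the gravity component (it encodes orientation, hence posture).
    """
    sos = signal.butter(4, _HIGHPASS_HZ, btype="high", fs=raw.fs, output="sos")
    highpassed = _filtfilt_axes(raw, sos)
    out = condition_signal(highpassed)
    out.gravity_corrected = True
    return out


def compute_vm(gc: TriaxialRecording, mode: str = "norm") -> np.ndarray:
    """Per-sample movement intensity from the gravity-corrected signals.

    ``norm`` is the Euclidean norm sqrt(x^2+y^2+z^2); ``rms`` divides by
    sqrt(3). The two differ by a constant that is absorbed by the VM slope
    coefficients downstream.
    """
    if not gc.gravity_corrected:
        raise ValueError("compute_vm requires a gravity-corrected recording")
    vm = np.sqrt(gc.ax**2 + gc.ay**2 + gc.az**2)
    if mode == "rms":
        vm = vm / np.sqrt(3.0)
    elif mode != "norm":
        raise ValueError("mode must be 'norm' or 'rms'")
    return vm


def epoch_count(duration_s: float, epoch_len_s: float = 6.0, step_s: float = 3.0) -> int:
    """Number of full epochs in a recording: floor((T - L)/step) + 1."""
    if duration_s < epoch_len_s:
        return 0
    return int(np.floor((duration_s - epoch_len_s) / step_s + 1e-9)) + 1


def window_count(duration_s: float, window_len_s: float = 30.0) -> int:
    return int(np.floor(duration_s / window_len_s + 1e-9))


def make_epochs(
    cond: TriaxialRecording,
    vm: np.ndarray,
    subject: str = "s0",
    config: RunConfig | None = None,
) -> EpochSet:
    """Cut the conditioned signals and VM into overlapping epochs."""
    cfg = config or RunConfig()
    n_len = int(round(cfg.epoch_len_s * cond.fs))
    n_step = int(round(cfg.epoch_step_s * cond.fs))
    if cond.n_samples < n_len:
        raise TooShortError(
            f"recording of {cond.duration_s:.1f} s shorter than one "
            f"{cfg.epoch_len_s:.0f}-s epoch"
        )
    xyz = cond.xyz
    n = (cond.n_samples - n_len) // n_step + 1
    x_view = sliding_window_view(xyz, n_len, axis=0)[::n_step]  # (n, 3, n_len)
    vm_view = sliding_window_view(np.asarray(vm, dtype=float), n_len)[::n_step]
    starts = np.arange(n) * cfg.epoch_step_s
    return EpochSet(
        subject=subject,
        start_s=starts,
        x=np.ascontiguousarray(x_view[:n].transpose(0, 2, 1)),
        vm=np.ascontiguousarray(vm_view[:n]),
    )


def label_epochs(
    epochs: EpochSet, schedule: list[ProtocolEvent], config: RunConfig | None = None
) -> np.ndarray:
    """True activity label per epoch: the scheduled class at the epoch midpoint.

    Epochs falling in between-condition gaps are labelled ``unknown`` and are
    excluded from classifier training.
    """
    cfg = config or RunConfig()
    mids = epochs.start_s + cfg.epoch_len_s / 2.0
    labels = np.full(epochs.n_epochs, UNKNOWN, dtype=object)
    for ev in schedule:
        inside = (mids >= ev.start_s) & (mids < ev.end_s)
        labels[inside] = ev.activity_class
    epochs.label_true = labels
    return labels


def _majority(labels: np.ndarray) -> tuple[str, bool]:
    """Majority label with fixed class-priority tie-break; True when tied."""
    known = [l for l in labels if l != UNKNOWN]
    if not known:
        return UNKNOWN, False
    counts = {c: 0 for c in ALL_CLASSES}
    for l in known:
        counts[l] += 1
    best = max(counts.values())
    winners = [c for c in ALL_CLASSES if counts[c] == best]
    return winners[0], len(winners) > 1


def _event_at(schedule: list[ProtocolEvent], t: float) -> int:
    for i, ev in enumerate(schedule):
        if ev.start_s <= t < ev.end_s:
            return i
    return -1


def make_windows(
    epochs: EpochSet,
    vm: np.ndarray,
    beats: BeatSeries | None,
    schedule: list[ProtocolEvent],
    config: RunConfig | None = None,
    fs: float = TARGET_FS,
) -> pd.DataFrame:
    """Aggregate epochs, VM and heartbeats into non-overlapping 30-s windows.

    Per window: mean VM over its samples, majority-voted activity label from
    the epochs starting inside it, condition/stress/baseline flags from the
    schedule at the window midpoint, and mean heart rate from the corrected
    beat series (windows with fewer than 10 usable intervals are HR-invalid).
    """
    from .cardiac import window_hr  # local import to keep modules acyclic

    cfg = config or RunConfig()
    vm = np.asarray(vm, dtype=float)
    duration = len(vm) / fs
    n_win = window_count(duration, cfg.window_len_s)
    wlen = cfg.window_len_s
    samples_per_win = int(round(wlen * fs))

    preds = epochs.label_pred if epochs.label_pred is not None else epochs.label_true
    rows = []
    for w in range(n_win):
        t0 = w * wlen
        in_w = (epochs.start_s >= t0) & (epochs.start_s < t0 + wlen)
        if preds is not None and in_w.any():
            label, tie = _majority(preds[in_w])
        else:
            label, tie = UNKNOWN, False
        mid = t0 + wlen / 2.0
        ev_i = _event_at(schedule, mid)
        ev = schedule[ev_i] if ev_i >= 0 else None
        rows.append(
            {
                "subject": epochs.subject,
                "window_idx": w,
                "start_s": t0,
                "mean_hr_bpm": np.nan,
                "mean_vm_g": float(np.mean(vm[w * samples_per_win:(w + 1) * samples_per_win])),
                "lag_vm_g": np.nan,
                "activity_pred": label,
                "activity_true": ev.activity_class if ev is not None else UNKNOWN,
                "condition": ev.label if ev is not None else "",
                "condition_idx": ev_i,
                "is_stress": bool(ev.is_stress) if ev is not None else False,
                "is_baseline": bool(ev.is_baseline) if ev is not None else False,
                "hr_valid": False,
                "lag_valid": False,
                "tie": tie,
            }
        )
    windows = pd.DataFrame(rows)
    windows["valid"] = [bool(((epochs.start_s >= w * wlen) & (epochs.start_s < (w + 1) * wlen)).any()) for w in range(n_win)]
    if beats is not None:
        windows = window_hr(beats, windows, config=cfg)
    return windows


def add_lagged_vm(windows: pd.DataFrame, lag_windows: int = 6) -> pd.DataFrame:
    """Mean VM over the preceding ``lag_windows`` windows, per subject.

    The first ``lag_windows`` windows of each subject have no full history
    and are flagged lag-invalid (they are removed before fitting the lagged
    model).
    """
    windows = windows.sort_values(["subject", "window_idx"]).reset_index(drop=True)
    out = []
    for _, grp in windows.groupby("subject", sort=False):
        vm = grp["mean_vm_g"].to_numpy()
        lag = np.full(len(vm), np.nan)
        for i in range(lag_windows, len(vm)):
            lag[i] = np.mean(vm[i - lag_windows:i])
        grp = grp.copy()
        grp["lag_vm_g"] = lag
        grp["lag_valid"] = ~np.isnan(lag)
        out.append(grp)
    return pd.concat(out, ignore_index=True)
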