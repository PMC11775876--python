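"""Convenience drivers tying the processing stages together."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .cardiac import correct_beats, flag_deviant_beats
from .config import RunConfig
from .core import BeatSeries, EpochSet, ProtocolEvent, TriaxialRecording
from .preprocess import (
    add_lagged_vm,
    compute_vm,
    condition_signal,
    gravity_correct,
    label_epochs,
    make_epochs,
    make_windows,
)


def process_subject(
    raw: TriaxialRecording,
    beats: BeatSeries | None,
    schedule: list[ProtocolEvent],
    subject: str = "s0",
    config: RunConfig | None = None,
) -> tuple[EpochSet, pd.DataFrame]:
    """Raw recording + beat series -> labelled epochs and 30-s window table.

    Conditions the signals, computes the gravity-corrected VM, screens the
    beat series for deviant intervals, and aggregates everything into
    windows with lagged VM. Epoch predictions are left to the activity
    stage; window labels fall back to the true epoch labels until
    predictions are attached.
    """
    cfg = config or RunConfig()
    cond = condition_signal(raw)
    vm = compute_vm(gravity_correct(raw), mode=cfg.vm_mode)
    epochs = make_epochs(cond, vm, subject=subject, config=cfg)
    label_epochs(epochs, schedule, config=cfg)
    if beats is not None:
        flags = flag_deviant_beats(beats)
        beats = correct_beats(beats, flags)
    windows = make_windows(epochs, vm, beats, schedule, config=cfg)
    windows = add_lagged_vm(windows, cfg.lag_windows)
    return epochs, windows


def attach_predictions(
    windows: pd.DataFrame, epochs: EpochSet, config: RunConfig | None = None
) -> pd.DataFrame:
    """Refresh window labels by majority vote over per-epoch predictions.

    Call after the activity stage has set ``epochs.label_pred``; VM, HR and
    schedule columns are left untouched.
    """
    from .preprocess import _majority

    cfg = config or RunConfig()
    if epochs.label_pred is None:
        raise ValueError("epochs carry no predictions")
    out = windows.copy()
    wlen = cfg.window_len_s
    for i in out.index:
        t0 = out.at[i, "start_s"]
        in_w = (epochs.start_s >= t0) & (epochs.start_s < t0 + wlen)
        label, tie = _majority(epochs.label_pred[in_w])
        out.at[i, "activity_pred"] = label
        out.at[i, "tie"] = tie
    return out
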