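"""CSV readers/writers for recordings, schedules, heartbeats and windows.

All on-disk numerics are plain comma-separated UTF-8 with a header row, so
fixtures stay inspectable and diff-able. Every writer round-trips through
its reader to 1e-9 on numeric fields.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ALL_CLASSES,
    UNKNOWN,
    BeatSeries,
    ProtocolEvent,
    TriaxialRecording,
    WINDOW_COLUMNS,
)
from .errors import DataError, FormatError, ScheduleError

_ACCEL_COLS = ["time_s", "ax_g", "ay_g", "az_g"]
_SCHEDULE_COLS = ["label", "start_s", "end_s", "activity_class", "is_stress", "is_baseline"]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {missing}")


def read_accel_csv(path: str | Path) -> TriaxialRecording:
    """Read a raw triaxial recording, inferring the sampling rate.

    Requires a strictly monotone time column on a uniform grid (interval
    jitter below 1e-6 s); non-uniform sampling is rejected.
    """
    df = pd.read_csv(path)
    _require_columns(df, _ACCEL_COLS, f"accelerometer file {path}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise DataError(f"{path}: need at least 2 samples to infer sampling rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError(f"{path}: time_s must be strictly increasing")
    if dt.max() - dt.min() > 1e-6:
        raise DataError(f"{path}: non-uniform sampling interval")
    fs = 1.0 / float(np.mean(dt))
    return TriaxialRecording(
        ax=df["ax_g"].to_numpy(dtype=float),
        ay=df["ay_g"].to_numpy(dtype=float),
        az=df["az_g"].to_numpy(dtype=float),
        fs=fs,
    )


def write_accel_csv(path: str | Path, rec: TriaxialRecording) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    pd.DataFrame(
        {"time_s": t, "ax_g": rec.ax, "ay_g": rec.ay, "az_g": rec.az}
    ).to_csv(path, index=False, float_format="%.10g")


def validate_events(events: list[ProtocolEvent]) -> list[ProtocolEvent]:
    """Check time-ordering and non-overlap; gaps between events are allowed."""
    for prev, nxt in zip(events, events[1:]):
        if nxt.start_s < prev.end_s:
            raise ScheduleError(
                f"events {prev.label!r} and {nxt.label!r} overlap "
                f"({prev.end_s} > {nxt.start_s})"
            )
    return events


def read_schedule_csv(path: str | Path) -> list[ProtocolEvent]:
    """Read a protocol schedule into a validated, time-ordered event list."""
    df = pd.read_csv(path)
    _require_columns(df, _SCHEDULE_COLS, f"schedule file {path}")
    events = []
    for row in df.itertuples(index=False):
        cls = str(row.activity_class)
        if cls not in ALL_CLASSES and cls != UNKNOWN:
            raise FormatError(f"{path}: unknown activity_class token {cls!r}")
        events.append(
            ProtocolEvent(
                label=str(row.label),
                start_s=float(row.start_s),
                end_s=float(row.end_s),
                activity_class=cls,
                is_stress=bool(row.is_stress),
                is_baseline=bool(row.is_baseline),
            )
        )
    events.sort(key=lambda e: e.start_s)
    return validate_events(events)


def write_schedule_csv(path: str | Path, events: list[ProtocolEvent]) -> None:
    pd.DataFrame(
        [
            {
                "label": e.label,
                "start_s": e.start_s,
                "end_s": e.end_s,
                "activity_class": e.activity_class,
                "is_stress": e.is_stress,
                "is_baseline": e.is_baseline,
            }
            for e in events
        ],
        columns=_SCHEDULE_COLS,
    ).to_csv(path, index=False, float_format="%.10g")


def read_beats_csv(path: str | Path) -> BeatSeries:
    """Read R-peak times (ms); intervals are derived on construction."""
    df = pd.read_csv(path)
    _require_columns(df, ["r_peak_ms"], f"beats file {path}")
    peaks = df["r_peak_ms"].to_numpy(dtype=float)
    if np.any(np.diff(peaks) <= 0):
        raise DataError(f"{path}: r_peak_ms must be strictly increasing")
    return BeatSeries(r_peak_ms=peaks)


def write_beats_csv(path: str | Path, beats: BeatSeries) -> None:
    pd.DataFrame({"r_peak_ms": beats.r_peak_ms}).to_csv(
        path, index=False, float_format="%.10g"
    )


def write_ibi_csv(path: str | Path, beats: BeatSeries) -> None:
    pd.DataFrame({"ibi_ms": beats.ibi_ms, "flag": beats.flags}).to_csv(
        path, index=False, float_format="%.10g"
    )


def write_windows_csv(path: str | Path, windows: pd.DataFrame) -> None:
    cols = [c for c in WINDOW_COLUMNS if c in windows.columns]
    extra = [c for c in windows.columns if c not in cols]
    windows[cols + extra].to_csv(path, index=False, float_format="%.10g")


def read_windows_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["subject", "window_idx", "start_s"], f"window file {path}")
    return df


def write_run_manifest(path: str | Path, seed: int, config_hash: str, **extra) -> None:
    """Record the RNG seed and config digest of a pipeline run."""
    payload = {"rng_seed": int(seed), "config_hash": config_hash, **extra}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
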