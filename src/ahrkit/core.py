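"""Core data containers shared by all pipeline stages.

Time convention: seconds from recording start, 0-based; all intervals are
half-open ``[start, end)`` so every sample, epoch and heartbeat belongs to
exactly one window.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Activity taxonomy. The order below is also the fixed tie-break priority of
# the majority rule (earlier class wins a tied vote).
STATIC_CLASSES: tuple[str, ...] = ("lying", "sitting", "standing")
DYNAMIC_CLASSES: tuple[str, ...] = ("walking", "jogging", "cycling", "stairs")
ALL_CLASSES: tuple[str, ...] = STATIC_CLASSES + DYNAMIC_CLASSES
UNKNOWN = "unknown"

#: Underlying posture of each activity class (used by the posture-only HR
#: model: locomotion happens upright, ergometer cycling seated).
POSTURE_OF: dict[str, str] = {
    "lying": "lying",
    "sitting": "sitting",
    "standing": "standing",
    "walking": "standing",
    "jogging": "standing",
    "stairs": "standing",
    "cycling": "sitting",
}

#: Column order of the per-window table produced by the pipeline.
WINDOW_COLUMNS = [
    "subject",
    "window_idx",
    "start_s",
    "mean_hr_bpm",
    "mean_vm_g",
    "lag_vm_g",
    "activity_pred",
    "activity_true",
    "condition",
    "condition_idx",
    "is_stress",
    "is_baseline",
    "hr_valid",
    "lag_valid",
    "tie",
]


@dataclass
class TriaxialRecording:
    """Sampled 3-axis acceleration in g.

    Axes follow the hip-worn device convention: x anterior-posterior,
    y vertical, z mediolateral.
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    gravity_corrected: bool = False

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("axes must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.ax)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def xyz(self) -> np.ndarray:
        """Samples as an (n, 3) array."""
        return np.column_stack([self.ax, self.ay, self.az])

    def copy(self) -> "TriaxialRecording":
        return replace(self, ax=self.ax.copy(), ay=self.ay.copy(), az=self.az.copy())


@dataclass
class EpochSet:
    """Stacked 6-s classification epochs for one subject.

    ``x`` holds the conditioned (gravity-retaining) samples, shape
    (n_epochs, samples_per_epoch, 3); ``vm`` the gravity-corrected vector
    magnitude, shape (n_epochs, samples_per_epoch).
    """

    subject: str
    start_s: np.ndarray
    x: np.ndarray
    vm: np.ndarray
    label_true: np.ndarray | None = None
    label_pred: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.x.ndim != 3 or self.x.shape[2] != 3:
            raise ValueError("x must have shape (n, samples, 3)")
        if self.vm.shape != self.x.shape[:2]:
            raise ValueError("vm shape must match x")

    @property
    def n_epochs(self) -> int:
        return self.x.shape[0]


@dataclass
class ProtocolEvent:
    """One scheduled experimental condition."""

    label: str
    start_s: float
    end_s: float
    activity_class: str = UNKNOWN
    is_stress: bool = False
    is_baseline: bool = False

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"event {self.label!r}: end_s must exceed start_s")
        if self.activity_class not in ALL_CLASSES and self.activity_class != UNKNOWN:
            raise ValueError(f"unknown activity class {self.activity_class!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BeatSeries:
    """R-peak times in ms and the derived inter-beat intervals.

    ``flags`` marks each interval as ``ok``, ``interpolated`` or ``excluded``
    after artifact screening; ``ibi_ms`` holds the (possibly interpolated)
    interval durations.
    """

    r_peak_ms: np.ndarray
    ibi_ms: np.ndarray = field(default=None)  # type: ignore[assignment]
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.r_peak_ms = np.asarray(self.r_peak_ms, dtype=float)
        if np.any(np.diff(self.r_peak_ms) <= 0):
            raise ValueError("r_peak_ms must be strictly increasing")
        if self.ibi_ms is None:
            self.ibi_ms = np.diff(self.r_peak_ms)
        else:
            self.ibi_ms = np.asarray(self.ibi_ms, dtype=float)
        if self.flags is None:
            self.flags = np.full(len(self.ibi_ms), "ok", dtype=object)

    @property
    def n_beats(self) -> int:
        return len(self.r_peak_ms)
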