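"""Coupled accelerometer + heartbeat simulator with known ground truth.

A subject is a protocol schedule plus generator parameters. Acceleration is
gravity orientation (per posture; dynamic classes are standing-oriented)
plus class-specific band-limited oscillation plus white noise, emitted raw
at 1000 Hz so the full conditioning/decimation chain is exercised. The
oscillation amplitude is slowly modulated within each condition so the
window VM varies within a class and all regression coefficients stay
identifiable even at zero noise.

Window-level true heart rate follows the lagged-covariate regression
structure the pipeline fits (intercept + VM slope + activity offsets +
lagged-VM slope), plus ``stress_effect`` BPM during scheduled stress
conditions and AR(1) noise. Heartbeats are emitted by integrate-and-fire
over the window rate; windowed beat rates match the true HR within 1 BPM
(a discretisation contract, tested).

Two granularities:

- :func:`generate_subject` — full raw-signal subject (recording + beats);
- :func:`generate_windows` / ``generate_cohort(..., level="windows")`` —
  window-level fast path producing the window table directly, for
  regression/detection studies where the signal chain is not under test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .core import (
    DYNAMIC_CLASSES,
    STATIC_CLASSES,
    UNKNOWN,
    BeatSeries,
    ProtocolEvent,
    TriaxialRecording,
)
from .preprocess import (
    TARGET_FS,
    add_lagged_vm,
    compute_vm,
    gravity_correct,
    window_count,
)

RAW_FS = 1000.0

#: Coefficient order of the generating regression.
BETA_NAMES = (
    "const", "vm", "sitting", "standing", "walking", "jogging", "cycling",
    "stairs", "lag_vm",
)

#: Default generating coefficients (BPM, BPM/g): intercept, concurrent-VM
#: slope, activity offsets relative to lying, lagged-VM slope.
DEFAULT_BETAS = (69.1, 36.0, 12.9, 19.8, 18.6, 22.6, 33.7, 34.3, 58.6)

#: Between-subject SDs of the random effects around DEFAULT_BETAS.
DEFAULT_BETA_RE_SD = (8.0, 6.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 8.0)

_ORIENTATIONS = {
    "lying": (-1.0, 0.0, 0.0),
    "sitting": (0.574, -0.819, 0.0),
    "standing": (0.0, -1.0, 0.0),
}

# (dominant frequency Hz, vertical amplitude g)
_KINEMATICS = {
    "walking": (2.0, 0.4),
    "jogging": (2.8, 0.9),
    "stairs": (1.8, 0.6),
    "cycling": (1.4, 0.15),
}

#: Window-mean VM (g) per class used by the window-level fast path; chosen
#: to sit near what the raw-signal path produces for the same kinematics.
_WINDOW_VM = {
    "lying": 0.006,
    "sitting": 0.008,
    "standing": 0.010,
    "walking": 0.30,
    "jogging": 0.68,
    "cycling": 0.12,
    "stairs": 0.46,
}


@dataclass
class GeneratorParams:
    """All knobs of the simulator; defaults are the packaged study conditions."""

    betas: tuple = DEFAULT_BETAS
    beta_re_sd: tuple = DEFAULT_BETA_RE_SD
    stress_effect_bpm: float = 10.0
    stress_effect_range: tuple[float, float] | None = None  # per-subject U(lo, hi)
    hr_ar_coef: float = 0.6
    hr_noise_sd_bpm: float = 2.4  # AR(1) innovation SD; stationary SD ~3 BPM
    accel_noise_static_g: float = 0.015
    accel_noise_dynamic_g: float = 0.05
    vm_modulation_depth: float = 0.25
    vm_modulation_period_s: float = 75.0
    window_vm_jitter_g: float = 0.02
    lag_windows: int = 6

    def __post_init__(self) -> None:
        if not 0 <= self.hr_ar_coef < 1:
            raise ValueError("AR(1) coefficient must be in [0, 1)")
        if len(self.betas) != len(BETA_NAMES):
            raise ValueError(f"betas must have {len(BETA_NAMES)} entries")
        for v in (self.hr_noise_sd_bpm, self.accel_noise_static_g,
                  self.accel_noise_dynamic_g, self.window_vm_jitter_g):
            if v < 0:
                raise ValueError("noise SDs must be non-negative")


@dataclass
class SubjectData:
    """One simulated subject with its complete ground truth."""

    subject: str
    schedule: list[ProtocolEvent]
    betas: dict
    stress_effect_bpm: float
    seed: int
    truth_windows: pd.DataFrame  # window_idx, start_s, class, vm, lag_vm, hr_true, is_stress
    recording: TriaxialRecording | None = None
    beats: BeatSeries | None = None
    windows: pd.DataFrame | None = None  # fast path: analysis-ready window table


@dataclass
class CohortBundle:
    subjects: list[SubjectData]
    schedule: list[ProtocolEvent]
    params: GeneratorParams
    seed: int

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": len(self.subjects),
            "subjects": {
                s.subject: {
                    "seed": s.seed,
                    "betas": s.betas,
                    "stress_effect_bpm": s.stress_effect_bpm,
                }
                for s in self.subjects
            },
        }

    def all_windows(self) -> pd.DataFrame:
        return pd.concat([s.windows for s in self.subjects], ignore_index=True)


def _class_at(schedule: list[ProtocolEvent], t: float) -> tuple[str, bool]:
    for ev in schedule:
        if ev.start_s <= t < ev.end_s:
            return ev.activity_class, ev.is_stress
    return UNKNOWN, False


def _window_classes(
    schedule: list[ProtocolEvent], n_win: int, wlen: float
) -> tuple[np.ndarray, np.ndarray]:
    classes = np.empty(n_win, dtype=object)
    stress = np.zeros(n_win, dtype=bool)
    for w in range(n_win):
        classes[w], stress[w] = _class_at(schedule, w * wlen + wlen / 2)
    return classes, stress


def _true_hr(
    vm: np.ndarray,
    classes: np.ndarray,
    stress: np.ndarray,
    betas: dict,
    stress_effect: float,
    ar_coef: float,
    noise_sd: float,
    lag_windows: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Window HR from the generating regression plus stress and AR(1) noise.

    The generator's lag term uses the mean over available preceding windows
    (so HR is defined from the first window on); the fitted model only ever
    uses windows with a complete lag history.
    """
    n = len(vm)
    lag = np.empty(n)
    for i in range(n):
        lo = max(0, i - lag_windows)
        lag[i] = vm[lo:i].mean() if i > 0 else vm[0]
    offsets = np.array(
        [betas.get(c, 0.0) if c in BETA_NAMES else 0.0 for c in classes]
    )
    hr = betas["const"] + betas["vm"] * vm + offsets + betas["lag_vm"] * lag
    hr = hr + stress_effect * stress.astype(float)
    noise = np.zeros(n)
    if noise_sd > 0:
        e = rng.normal(0.0, noise_sd, size=n)
        for i in range(n):
            noise[i] = (ar_coef * noise[i - 1] if i > 0 else 0.0) + e[i]
    return hr + noise, lag


def _emit_beats(hr: np.ndarray, wlen: float, rng: np.random.Generator) -> BeatSeries:
    """Integrate-and-fire beat train over the piecewise-constant window rate."""
    peaks = [0.0]
    t = 0.0
    total = len(hr) * wlen
    while True:
        w = min(int(t // wlen), len(hr) - 1)
        ibi_s = 60.0 / max(hr[w], 20.0)
        t += ibi_s
        if t > total:
            break
        peaks.append(t)
    return BeatSeries(r_peak_ms=np.asarray(peaks) * 1000.0)


def _betas_for_subject(
    params: GeneratorParams, rng: np.random.Generator
) -> dict:
    draw = np.asarray(params.betas) + rng.normal(0, params.beta_re_sd)
    # slopes stay positive: physiology, not estimation noise
    draw[1] = max(draw[1], 5.0)
    draw[-1] = max(draw[-1], 5.0)
    return dict(zip(BETA_NAMES, draw.tolist()))


def _stress_effect_for_subject(
    params: GeneratorParams, rng: np.random.Generator
) -> float:
    if params.stress_effect_range is not None:
        lo, hi = params.stress_effect_range
        return float(rng.uniform(lo, hi))
    return float(params.stress_effect_bpm)


def generate_subject(
    schedule: list[ProtocolEvent],
    params: GeneratorParams | None = None,
    seed: int = 0,
    subject: str = "s0",
    config: RunConfig | None = None,
) -> SubjectData:
    """Full raw-signal subject: 1000-Hz recording, beat series, ground truth."""
    if not schedule:
        raise ValueError("schedule is empty")
    params = params or GeneratorParams()
    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    betas = _betas_for_subject(params, rng)
    stress_effect = _stress_effect_for_subject(params, rng)

    total_s = schedule[-1].end_s
    n_raw = int(round(total_s * RAW_FS))
    xyz = np.zeros((n_raw, 3))
    # background (gaps): quiet standing
    xyz[:] = _ORIENTATIONS["standing"]
    if params.accel_noise_static_g > 0:
        xyz += rng.normal(0, params.accel_noise_static_g, size=xyz.shape)
    for ev in schedule:
        i0, i1 = int(round(ev.start_s * RAW_FS)), int(round(ev.end_s * RAW_FS))
        t = np.arange(i0, i1) / RAW_FS
        cls = ev.activity_class
        if cls in STATIC_CLASSES or cls == UNKNOWN:
            seg = np.tile(_ORIENTATIONS.get(cls, _ORIENTATIONS["standing"]), (len(t), 1))
            noise_sd = params.accel_noise_static_g
        else:
            f, amp = _KINEMATICS[cls]
            phase = rng.uniform(0, 2 * np.pi)
            mod = 1.0 + params.vm_modulation_depth * np.sin(
                2 * np.pi * (t - ev.start_s) / params.vm_modulation_period_s + phase
            )
            a = amp * mod
            seg = np.tile(_ORIENTATIONS["standing"], (len(t), 1))
            seg[:, 1] += a * np.sin(2 * np.pi * f * t)
            seg[:, 0] += 0.5 * a * np.sin(2 * np.pi * f * t + 1.1)
            seg[:, 2] += 0.3 * a * np.sin(2 * np.pi * f * t + 2.3)
            if cls == "stairs":
                seg[:, 1] += 0.4 * a * np.sin(2 * np.pi * 0.5 * f * t + 0.7)
            noise_sd = params.accel_noise_dynamic_g
        if noise_sd > 0:
            seg = seg + rng.normal(0, noise_sd, size=seg.shape)
        xyz[i0:i1] = seg
    rec = TriaxialRecording(ax=xyz[:, 0], ay=xyz[:, 1], az=xyz[:, 2], fs=RAW_FS)

    # ground-truth windows from the generator's own VM
    gc = gravity_correct(rec)
    vm = compute_vm(gc, mode=cfg.vm_mode)
    wlen = cfg.window_len_s
    n_win = window_count(len(vm) / TARGET_FS, wlen)
    spw = int(round(wlen * TARGET_FS))
    vm_win = np.array([vm[w * spw:(w + 1) * spw].mean() for w in range(n_win)])
    classes, stress = _window_classes(schedule, n_win, wlen)
    hr, lag = _true_hr(
        vm_win, classes, stress, betas, stress_effect,
        params.hr_ar_coef, params.hr_noise_sd_bpm, params.lag_windows, rng,
    )
    truth = pd.DataFrame(
        {
            "window_idx": np.arange(n_win),
            "start_s": np.arange(n_win) * wlen,
            "activity_true": classes,
            "vm_true": vm_win,
            "lag_vm_true": lag,
            "hr_true": hr,
            "is_stress": stress,
        }
    )
    beats = _emit_beats(hr, wlen, rng)
    return SubjectData(
        subject=subject,
        schedule=schedule,
        betas=betas,
        stress_effect_bpm=stress_effect,
        seed=seed,
        truth_windows=truth,
        recording=rec,
        beats=beats,
    )


def generate_windows(
    schedule: list[ProtocolEvent],
    params: GeneratorParams | None = None,
    seed: int = 0,
    subject: str = "s0",
    config: RunConfig | None = None,
) -> SubjectData:
    """Window-level fast path: analysis-ready window table, no raw signals."""
    if not schedule:
        raise ValueError("schedule is empty")
    params = params or GeneratorParams()
    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    betas = _betas_for_subject(params, rng)
    stress_effect = _stress_effect_for_subject(params, rng)

    wlen = cfg.window_len_s
    n_win = window_count(schedule[-1].end_s, wlen)
    classes, stress = _window_classes(schedule, n_win, wlen)
    starts = np.arange(n_win) * wlen
    base = np.array([_WINDOW_VM.get(c, 0.01) for c in classes])
    phase = rng.uniform(0, 2 * np.pi)
    mod = 1.0 + params.vm_modulation_depth * np.sin(
        2 * np.pi * starts / params.vm_modulation_period_s + phase
    )
    vm = base * mod + rng.normal(0, params.window_vm_jitter_g, size=n_win) * (base > 0.05)
    vm = np.clip(vm, 0.0, None)
    hr, lag = _true_hr(
        vm, classes, stress, betas, stress_effect,
        params.hr_ar_coef, params.hr_noise_sd_bpm, params.lag_windows, rng,
    )
    conditions = [_event_index(schedule, s + wlen / 2) for s in starts]
    windows = pd.DataFrame(
        {
            "subject": subject,
            "window_idx": np.arange(n_win),
            "start_s": starts,
            "mean_hr_bpm": hr,
            "mean_vm_g": vm,
            "lag_vm_g": np.nan,
            "activity_pred": classes,
            "activity_true": classes,
            "condition": [
                schedule[i].label if i >= 0 else "" for i in conditions
            ],
            "condition_idx": conditions,
            "is_stress": stress,
            "is_baseline": [
                schedule[i].is_baseline if i >= 0 else False for i in conditions
            ],
            "hr_valid": True,
            "lag_valid": False,
            "tie": False,
        }
    )
    windows = add_lagged_vm(windows, cfg.lag_windows)
    truth = pd.DataFrame(
        {
            "window_idx": np.arange(n_win),
            "start_s": starts,
            "activity_true": classes,
            "vm_true": vm,
            "lag_vm_true": lag,
            "hr_true": hr,
            "is_stress": stress,
        }
    )
    return SubjectData(
        subject=subject,
        schedule=schedule,
        betas=betas,
        stress_effect_bpm=stress_effect,
        seed=seed,
        truth_windows=truth,
        windows=windows,
    )


def _event_index(schedule: list[ProtocolEvent], t: float) -> int:
    for i, ev in enumerate(schedule):
        if ev.start_s <= t < ev.end_s:
            return i
    return -1


def generate_cohort(
    n_subjects: int,
    schedule: list[ProtocolEvent],
    params: GeneratorParams | None = None,
    seed: int = 0,
    level: str = "windows",
    config: RunConfig | None = None,
) -> CohortBundle:
    """Cohort of subjects with per-subject seeds derived from the master seed.

    ``level='windows'`` uses the fast window-level path; ``level='raw'``
    generates full recordings and beat series.
    """
    if n_subjects < 3:
        raise ValueError("a cohort needs at least 3 subjects")
    params = params or GeneratorParams()
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2**31)
    gen = generate_windows if level == "windows" else generate_subject
    subjects = [
        gen(schedule, params=params, seed=int(sub_seeds[i]),
            subject=f"s{i:03d}", config=config)
        for i in range(n_subjects)
    ]
    return CohortBundle(subjects=subjects, schedule=schedule, params=params, seed=seed)
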