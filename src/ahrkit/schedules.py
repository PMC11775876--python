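"""Packaged protocol schedules.

Two laboratory protocols mixing posture manipulations, physical activity and
mental-stress tasks, plus a compact demonstration protocol used for fast
synthetic benchmarks. Events are contiguous by default; an optional
``gap_s`` inserts unknown-activity gaps between conditions, mimicking the
instructed transitions of a real session.
"""
from __future__ import annotations

from .core import ProtocolEvent

# (label, duration_min, activity_class, is_stress, is_baseline)
_STUDY1_ROWS = [
    ("Baseline", 4, "sitting", False, True),
    ("Standing", 3, "standing", False, True),
    ("Lying down", 3, "lying", False, True),
    ("Sitting", 3, "sitting", False, True),
    ("Lying down", 3, "lying", False, True),
    ("Standing", 3, "standing", False, True),
    ("Sitting", 3, "sitting", False, False),
    ("Tone Avoidance", 3, "sitting", True, False),
    ("Walking outside at leisurely pace", 2, "walking", False, False),
    ("Walking outside while talking", 2, "walking", False, False),
    ("Walking stairs", 4, "stairs", False, False),
    ("Recovery (sitting)", 3, "sitting", False, False),
    ("Ergometer 50 Watt with 60 RPM", 4, "cycling", False, False),
    ("Ergometer 100 Watt with 60 RPM", 4, "cycling", False, False),
    ("Ergometer 150 Watt with 60 RPM", 4, "cycling", False, False),
    ("Recovery (sitting)", 3, "sitting", False, False),
    ("Treadmill (4.5-5 km/h)", 4, "walking", False, False),
    ("Treadmill (6-6.5 km/h)", 4, "walking", False, False),
    ("Treadmill (7.5-8 km/h)", 4, "jogging", False, False),
    ("Recovery (sitting)", 3, "sitting", False, False),
    ("Vacuum cleaning", 3, "walking", False, False),
    ("Moving plates", 3, "standing", False, False),
]

_STUDY2_ROWS = [
    ("Lying down", 3, "lying", False, True),
    ("Standing", 3, "standing", False, True),
    ("Sitting", 3, "sitting", False, True),
    ("Tone Avoidance", 4, "sitting", True, False),
    ("Recovery (sitting)", 2, "sitting", False, False),
    ("Short Sing-a-Song Stress Test", 6.5, "sitting", True, False),
    ("Recovery (sitting)", 2, "sitting", False, False),
    ("Paced Auditory Serial Addition Test", 4, "sitting", True, False),
    ("Recovery (sitting)", 2, "sitting", False, False),
    ("Raven's progressive matrices", 4, "sitting", True, False),
    ("Walking at natural pace", 2, "walking", False, False),
    ("Fast walking", 2, "walking", False, False),
    ("Cycling", 4, "cycling", False, False),
    ("Walking stairs", 4, "stairs", False, False),
    ("Recovery (standing)", 2, "standing", False, False),
    ("Dish washing", 2, "standing", False, False),
    ("Vacuum cleaning", 2, "walking", False, False),
    ("Recovery (sitting)", 2, "sitting", False, False),
    ("Tone Avoidance", 4, "sitting", True, False),
    ("Recovery (sitting)", 2, "sitting", False, False),
    ("Paced Auditory Serial Addition Test", 4, "sitting", True, False),
    ("Treadmill (4.5-5 km/h)", 4, "walking", False, False),
    ("Treadmill (6-6.5 km/h)", 4, "walking", False, False),
    ("Treadmill (7.5-8 km/h)", 4, "jogging", False, False),
    ("Treadmill (3.7-4 km/h)", 3, "walking", False, False),
    ("Recovery (sitting)", 3, "sitting", False, False),
]

# Desk-scale protocol covering all seven classes, with one stress task at
# rest and one directly after vigorous exercise (the situation in which a
# movement-corrected stress signal should beat raw heart rate).
_DEMO_ROWS = [
    ("Lying baseline", 1, "lying", False, True),
    ("Standing baseline", 1, "standing", False, True),
    ("Sitting baseline", 1, "sitting", False, True),
    ("Stress task A", 1, "sitting", True, False),
    ("Recovery (sitting)", 1, "sitting", False, False),
    ("Walking", 1, "walking", False, False),
    ("Jogging", 1, "jogging", False, False),
    ("Walking stairs", 1, "stairs", False, False),
    ("Cycling", 1, "cycling", False, False),
    ("Stress task B", 1, "sitting", True, False),
    ("Recovery (sitting)", 1, "sitting", False, False),
]


def _build(rows, gap_s: float = 0.0) -> list[ProtocolEvent]:
    events = []
    t = 0.0
    for label, minutes, cls, stress, baseline in rows:
        start = t
        end = start + minutes * 60.0
        events.append(
            ProtocolEvent(
                label=label,
                start_s=start,
                end_s=end,
                activity_class=cls,
                is_stress=stress,
                is_baseline=baseline,
            )
        )
        t = end + gap_s
    return events


def study1_schedule(gap_s: float = 0.0) -> list[ProtocolEvent]:
    """22-condition protocol with duplicated posture baselines and ergometry."""
    return _build(_STUDY1_ROWS, gap_s)


def study2_schedule(gap_s: float = 0.0) -> list[ProtocolEvent]:
    """26-condition protocol with six mental-stress tasks (one baseline per posture)."""
    return _build(_STUDY2_ROWS, gap_s)


def demo_schedule(
    gap_s: float = 0.0, condition_len_s: float = 60.0
) -> list[ProtocolEvent]:
    """Compact 11-condition protocol for fast synthetic benchmarks."""
    rows = [
        (label, condition_len_s / 60.0, cls, stress, baseline)
        for label, _, cls, stress, baseline in _DEMO_ROWS
    ]
    return _build(rows, gap_s)


def repeated_demo_schedule(
    n_blocks: int = 11, condition_len_s: float = 60.0
) -> list[ProtocolEvent]:
    """The demo protocol repeated back to back.

    Puts every class (including the lying reference) well past the lag
    warm-up, so all regression coefficients stay identifiable; used for
    parameter-recovery studies (11 blocks of 60-s conditions give a
    242-window subject).
    """
    rows = []
    for b in range(n_blocks):
        for label, _, cls, stress, baseline in _DEMO_ROWS:
            rows.append(
                (f"{label} [{b}]", condition_len_s / 60.0, cls, stress,
                 baseline and b == 0)
            )
    return _build(rows, 0.0)
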