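"""Shared fixtures: small synthetic recordings, cohorts and schedules."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ahrkit import RunConfig, TriaxialRecording, schedules, synth
from ahrkit.pipeline import process_subject


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def demo_schedule():
    return schedules.demo_schedule()


@pytest.fixture(scope="session")
def study2_schedule():
    return schedules.study2_schedule()


def make_recording(
    duration_s: float,
    fs: float = 1000.0,
    orientation=(0.0, -1.0, 0.0),
    tone_hz: float | None = None,
    tone_amp_g: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TriaxialRecording:
    """Constant-orientation recording with an optional vertical tone."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    xyz = np.tile(np.asarray(orientation, dtype=float), (n, 1))
    if tone_hz is not None:
        xyz[:, 1] += tone_amp_g * np.sin(2 * np.pi * tone_hz * t)
    if noise_sd > 0:
        xyz += rng.normal(0, noise_sd, size=xyz.shape)
    return TriaxialRecording(ax=xyz[:, 0], ay=xyz[:, 1], az=xyz[:, 2], fs=fs)


@pytest.fixture(scope="session")
def raw_subject(demo_schedule):
    """One fully simulated raw subject, processed through the whole chain."""
    sub = synth.generate_subject(demo_schedule, seed=42, subject="raw0")
    epochs, windows = process_subject(
        sub.recording, sub.beats, demo_schedule, subject="raw0"
    )
    return sub, epochs, windows


@pytest.fixture(scope="session")
def window_cohort(study2_schedule):
    """10-subject window-level cohort from the long protocol (fast path)."""
    return synth.generate_cohort(10, study2_schedule, seed=2024, level="windows")


def fitted_ahr_windows(cohort, schedule, model_id=4) -> pd.DataFrame:
    """Cross-validated Model-4 pHR, aHR and dHR for every cohort subject."""
    from ahrkit.ahr import compute_ahr, compute_delta_hr
    from ahrkit.hrmodel import fit_predict_cv

    outs = []
    for s in cohort.subjects:
        out, _ = fit_predict_cv(s.windows, model_id, seed=s.seed)
        outs.append(out)
    allw = pd.concat(outs, ignore_index=True)
    return compute_delta_hr(compute_ahr(allw), schedule)
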