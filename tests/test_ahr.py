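"""aHR, classic reactivity and the two validation analyses."""
import numpy as np
import pandas as pd
import pytest

from ahrkit import schedules, synth
from ahrkit.ahr import (
    between_subject_scatter,
    compute_ahr,
    compute_delta_hr,
    condition_summary,
    within_subject_detection,
)
from ahrkit.core import ProtocolEvent
from ahrkit.errors import AlignmentError
from ahrkit.hrmodel import fit_predict_cv


def simple_windows(subject="a", ohr=None, phr=None, cond_idx=None, stress=None,
                   n=None):
    n = n if n is not None else len(ohr)
    df = pd.DataFrame(
        {
            "subject": subject,
            "window_idx": range(n),
            "start_s": np.arange(n) * 30.0,
            "mean_hr_bpm": ohr if ohr is not None else np.full(n, 70.0),
            "mean_vm_g": 0.0,
            "lag_vm_g": 0.0,
            "activity_pred": "sitting",
            "activity_true": "sitting",
            "condition": "c",
            "condition_idx": cond_idx if cond_idx is not None else 0,
            "is_stress": stress if stress is not None else False,
            "is_baseline": False,
            "hr_valid": True,
            "lag_valid": True,
            "tie": False,
        }
    )
    if phr is not None:
        df["phr_bpm"] = phr
    return df


class TestComputeAHR:
    def test_basic_subtraction(self):
        w = simple_windows(ohr=[80.0], phr=[75.0])
        assert compute_ahr(w).loc[0, "ahr_bpm"] == 5.0

    def test_identity_when_phr_equals_ohr(self):
        ohr = np.random.default_rng(0).normal(80, 10, 20)
        w = simple_windows(ohr=ohr, phr=ohr)
        np.testing.assert_array_equal(compute_ahr(w)["ahr_bpm"], 0.0)

    def test_identity_ahr_plus_phr_is_ohr_bitwise(self):
        rng = np.random.default_rng(1)
        ohr, phr = rng.normal(80, 12, 50), rng.normal(78, 10, 50)
        w = compute_ahr(simple_windows(ohr=ohr, phr=phr))
        assert (w["ahr_bpm"] + w["phr_bpm"] == w["mean_hr_bpm"]).all()

    def test_missing_phr_rejected(self):
        with pytest.raises(AlignmentError):
            compute_ahr(simple_windows(ohr=[80.0]))


def two_baseline_schedule():
    """Study-1 style: two sitting baselines, then a stress task and walking."""
    return [
        ProtocolEvent("Sit base 1", 0, 60, "sitting", is_baseline=True),
        ProtocolEvent("Stand base", 60, 120, "standing", is_baseline=True),
        ProtocolEvent("Sit base 2", 120, 180, "sitting", is_baseline=True),
        ProtocolEvent("Stress", 180, 240, "sitting", is_stress=True),
        ProtocolEvent("Walk", 240, 300, "walking"),
        # deliberate gap 300-360, then one more condition
        ProtocolEvent("Recovery", 360, 420, "sitting"),
    ]


class TestDeltaHR:
    def make(self):
        sched = two_baseline_schedule()
        ohr = np.array([68, 68, 75, 75, 72, 72, 82, 82, 110, 112, 90, 95, 80, 80.0])
        cond = np.array([0, 0, 1, 1, 2, 2, 3, 3, 4, 4, -1, -1, 5, 5])
        stress = cond == 3
        w = simple_windows(ohr=ohr, cond_idx=cond, stress=stress, phr=ohr * 0 + 70)
        w["condition"] = ["c" if c >= 0 else "" for c in cond]
        return compute_delta_hr(w, sched), sched

    def test_two_sitting_baselines_averaged(self):
        out, _ = self.make()
        # sitting reference = mean(68, 72) = 70; stress windows oHR 82
        assert out.loc[6, "delta_hr_bpm"] == pytest.approx(12.0)

    def test_walking_uses_standing_baseline(self):
        out, _ = self.make()
        assert out.loc[8, "delta_hr_bpm"] == pytest.approx(110 - 75.0)

    def test_gap_windows_visualization_only(self):
        out, _ = self.make()
        assert out.loc[10, "visualization_only"]
        assert out.loc[10, "delta_hr_bpm"] == pytest.approx(90 - 92.5)
        assert not out.loc[6, "visualization_only"]


class TestConditionSummary:
    def test_affine_relation_gives_r_one_and_gap_excluded(self):
        sched = two_baseline_schedule()
        frames = []
        rng = np.random.default_rng(3)
        for i, subj in enumerate("abcde"):
            ohr = rng.normal(75, 2, 14) + np.where(
                np.arange(14) >= 6, 4.0 * i, 0.0
            )  # subject-dependent task reactivity
            cond = np.array([0, 0, 1, 1, 2, 2, 3, 3, 4, 4, -1, -1, 5, 5])
            w = simple_windows(subject=subj, ohr=ohr, cond_idx=cond,
                               stress=cond == 3)
            frames.append(w)
        allw = pd.concat(frames, ignore_index=True)
        allw["phr_bpm"] = allw["mean_hr_bpm"]  # placeholder
        allw = compute_delta_hr(compute_ahr(allw), sched)
        # aHR = dHR + 3 (same constant for everyone) -> r is exactly 1
        allw["ahr_bpm"] = allw["delta_hr_bpm"] + 3.0
        summ = condition_summary(allw, sched)
        stress_row = summ[summ["condition_idx"] == 3].iloc[0]
        assert stress_row["n"] == 5
        assert stress_row["r"] == pytest.approx(1.0)
        assert stress_row["ahr_mean"] == pytest.approx(
            stress_row["delta_hr_mean"] + 3.0
        )
        assert len(summ) == len(sched)

    def test_identical_subjects_give_zero_sd_and_undefined_r(self):
        sched = two_baseline_schedule()[:1]
        frames = [
            simple_windows(subject=s, ohr=np.full(4, 80.0), phr=np.full(4, 75.0))
            for s in "abc"
        ]
        allw = compute_delta_hr(compute_ahr(pd.concat(frames, ignore_index=True)),
                                sched)
        summ = condition_summary(allw, sched)
        assert summ.loc[0, "ahr_sd"] == 0.0
        assert np.isnan(summ.loc[0, "r"])

    def test_r_matches_formula_oracle(self):
        rng = np.random.default_rng(8)
        sched = [ProtocolEvent("c", 0, 120, "sitting", is_baseline=True)]
        frames = []
        for i in range(10):
            ohr = rng.normal(80, 5, 4)
            w = simple_windows(subject=f"s{i}", ohr=ohr,
                               phr=ohr - rng.normal(5, 3, 4))
            frames.append(w)
        allw = compute_delta_hr(compute_ahr(pd.concat(frames, ignore_index=True)),
                                sched)
        summ = condition_summary(allw, sched)
        per = allw.groupby("subject")[["delta_hr_bpm", "ahr_bpm"]].mean()
        d, a = per["delta_hr_bpm"].to_numpy(), per["ahr_bpm"].to_numpy()
        r_direct = (
            np.sum((d - d.mean()) * (a - a.mean()))
            / np.sqrt(np.sum((d - d.mean()) ** 2) * np.sum((a - a.mean()) ** 2))
        )
        assert summ.loc[0, "r"] == pytest.approx(r_direct, abs=1e-12)


class TestBetweenSubjectScatter:
    def test_heterogeneous_stress_effects_recovered(self, study2_schedule):
        # subject-specific stress effects U(0, 20); "correct" pHR from truth
        params = synth.GeneratorParams(stress_effect_range=(0.0, 20.0))
        cohort = synth.generate_cohort(15, study2_schedule, params=params,
                                       seed=31, level="windows")
        frames = []
        for s in cohort.subjects:
            w = s.windows.copy()
            w["phr_bpm"] = (
                w["mean_hr_bpm"]
                - s.stress_effect_bpm * w["is_stress"].astype(float)
            )
            frames.append(w)
        allw = compute_delta_hr(compute_ahr(pd.concat(frames, ignore_index=True)),
                                study2_schedule)
        sc = between_subject_scatter(allw, study2_schedule, 5)  # song stress test
        assert sc.r >= 0.9
        assert len(sc.points) == 15

    def test_constant_effect_gives_near_zero_r(self, study2_schedule):
        params = synth.GeneratorParams(stress_effect_bpm=10.0)
        cohort = synth.generate_cohort(30, study2_schedule, params=params,
                                       seed=13, level="windows")
        frames = []
        rng = np.random.default_rng(99)
        for s in cohort.subjects:
            w = s.windows.copy()
            # correct pHR plus independent noise: aHR carries no signal
            w["phr_bpm"] = (
                w["mean_hr_bpm"]
                - s.stress_effect_bpm * w["is_stress"].astype(float)
                + rng.normal(0, 3, len(w))
            )
            frames.append(w)
        allw = compute_delta_hr(compute_ahr(pd.concat(frames, ignore_index=True)),
                                study2_schedule)
        sc = between_subject_scatter(allw, study2_schedule, 5)
        assert abs(sc.r) < 0.45

    def test_centroid_is_componentwise_mean(self):
        sched = [
            ProtocolEvent("c", 0, 120, "sitting", is_stress=True, is_baseline=True)
        ]
        frames = [
            simple_windows(subject=s, ohr=np.full(4, 70.0 + i),
                           phr=np.full(4, 65.0), stress=True)
            for i, s in enumerate("abcd")
        ]
        allw = compute_delta_hr(compute_ahr(pd.concat(frames, ignore_index=True)),
                                sched)
        sc = between_subject_scatter(allw, sched, 0)
        assert sc.centroid[0] == pytest.approx(sc.points["ahr_mean"].mean())
        assert sc.centroid[1] == pytest.approx(sc.points["delta_hr_mean"].mean())


class TestWithinSubjectDetection:
    def detection_windows(self, n=20, n_stress=6, ahr_stress=10.0, subject="a",
                          seed=0):
        rng = np.random.default_rng(seed)
        stress = np.zeros(n, dtype=bool)
        stress[:n_stress] = True
        rng.shuffle(stress)
        ohr = np.full(n, 70.0)
        w = simple_windows(subject=subject, ohr=ohr, stress=stress)
        w["phr_bpm"] = 70.0
        w["ahr_bpm"] = np.where(stress, ahr_stress, 0.0) + rng.normal(0, 0.1, n)
        return w

    def test_perfect_separation_at_matching_threshold(self):
        w = self.detection_windows(n=20, n_stress=6)
        rep = within_subject_detection(w, threshold_fraction=0.30, signal="ahr")
        assert rep.summary["recall_mean"] == 1.0
        assert rep.summary["precision_mean"] == 1.0
        np.testing.assert_allclose(rep.mean_confusion.sum(axis=1), 1.0)

    def test_threshold_one_gives_full_recall_and_prevalence_precision(self):
        w = self.detection_windows(n=20, n_stress=6)
        rep = within_subject_detection(w, threshold_fraction=0.999, signal="ahr")
        assert rep.summary["recall_mean"] == 1.0
        assert rep.summary["precision_mean"] == pytest.approx(6 / 20)

    def test_ties_broken_earlier_window_first(self):
        w = simple_windows(ohr=np.full(10, 70.0), stress=[True] * 3 + [False] * 7)
        w["ahr_bpm"] = 5.0  # all tied
        rep = within_subject_detection(w, threshold_fraction=0.30, signal="ahr")
        # first 3 windows selected, which are exactly the stress windows
        assert rep.per_subject["recall"].iloc[0] == 1.0

    def test_subject_without_stress_excluded_and_logged(self):
        w1 = self.detection_windows(subject="a")
        w2 = self.detection_windows(subject="b", n_stress=0)
        rep = within_subject_detection(pd.concat([w1, w2], ignore_index=True),
                                       signal="ahr")
        assert rep.excluded_subjects == ["b"]
        assert list(rep.per_subject["subject"]) == ["a"]

    def test_confusion_rows_sum_to_one_for_every_subject(self):
        frames = [self.detection_windows(subject=f"s{i}", seed=i) for i in range(5)]
        rep = within_subject_detection(pd.concat(frames, ignore_index=True),
                                       signal="ahr")
        np.testing.assert_allclose(rep.mean_confusion.sum(axis=1), 1.0, atol=1e-9)

    def test_permutation_expectation_matches_threshold(self, study2_schedule):
        # signal independent of the ground truth: expected recall equals the
        # threshold fraction
        base = synth.generate_windows(study2_schedule, seed=0).windows
        rng = np.random.default_rng(123)
        recalls = []
        for _ in range(200):
            w = base.copy()
            w["ahr_bpm"] = rng.normal(0, 5, len(w))
            rep = within_subject_detection(w, threshold_fraction=0.30, signal="ahr")
            recalls.append(rep.summary["recall_mean"])
        assert np.mean(recalls) == pytest.approx(0.30, abs=0.03)
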