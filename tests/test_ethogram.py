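"""Interval annotation, the 5-min sleep rule, death QC and feature extraction."""

import math

import numpy as np
import pandas as pd
import pytest

from flypheno import ethogram
from flypheno.ethogram import (FlyTrack, INTERVAL, annotate_intervals,
                               corrected_velocity, detect_death,
                               extract_features, morning_anticipation,
                               score_sleep)
from conftest import make_annotations, make_track


class TestCorrectedVelocity:
    @pytest.mark.parametrize("disp, dtfps, expected", [
        (0.0042, 1.0, 1.0),          # displacement equal to the correction factor
        (0.25, 1.0, 0.25 / 0.0042),  # immobility threshold displacement
        (0.0, 1.0, 0.0),             # stationary fly convention
    ])
    def test_worked_examples(self, disp, dtfps, expected):
        assert corrected_velocity(disp, dt=dtfps, fps=1.0) == pytest.approx(expected)

    def test_reduces_to_linear_form(self, rng):
        disp = rng.uniform(0.01, 5.0, 100)
        v = corrected_velocity(disp, dt=0.5, fps=2.0)
        np.testing.assert_allclose(v, disp / (0.5 * 2.0 * 0.0042))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            corrected_velocity(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            corrected_velocity(1.0, 0.0, 1.0)


class TestAnnotateIntervals:
    def test_all_below_threshold_immobile(self):
        track = make_track([0.1] * 60)
        ann = annotate_intervals(track)
        assert not ann["moving"].any()

    def test_single_large_step_marks_one_window(self):
        disp = [0.05] * 59
        disp[30] = 0.30                      # lands in window 1 (frames 20-39)
        ann = annotate_intervals(make_track(disp))
        assert ann["moving"].tolist() == [False, True, False]

    def test_threshold_boundary_is_moving(self):
        # immobility requires displacement strictly below 0.25 mm
        disp = [0.05] * 59
        disp[10] = 0.25
        ann = annotate_intervals(make_track(disp))
        assert ann["moving"].iloc[0]

    def test_gap_marked_missing_not_interpolated(self):
        t = np.concatenate([np.arange(0, 10, 0.5), np.arange(30, 40, 0.5)])
        x = np.linspace(0, 5, t.size)
        track = FlyTrack("f", "wt", t, x, np.full(t.size, 1.0), fps=2.0)
        ann = annotate_intervals(track)
        assert ann["missing"].iloc[1] and ann["missing"].iloc[2]
        assert not ann["missing"].iloc[0]

    def test_translation_invariance(self, rng):
        disp = rng.uniform(0, 0.6, 119)
        a = annotate_intervals(make_track(disp))
        track = make_track(disp)
        track.x = track.x + 7.3
        b = annotate_intervals(track)
        pd.testing.assert_frame_equal(a, b)

    def test_fast_and_generic_paths_agree(self, rng):
        disp = rng.uniform(0, 0.6, 239)
        track = make_track(disp)
        fast = annotate_intervals(track)
        # nudge one timestamp by nothing detectable but break regularity flag
        irregular = FlyTrack("f0", "wt", track.t + 0.0, track.x, track.y, fps=2.0)
        irregular.t = irregular.t.copy()
        irregular.t[-1] += 1e-4
        generic = annotate_intervals(irregular)
        np.testing.assert_array_equal(fast["moving"], generic["moving"])
        np.testing.assert_allclose(fast["max_displacement"],
                                   generic["max_displacement"])


class TestScoreSleep:
    def test_run_longer_than_5min_is_one_bout(self):
        moving = np.ones(60, dtype=bool)
        moving[10:43] = False                # 33 intervals = 330 s
        ann, bouts = score_sleep(make_annotations(moving))
        assert len(bouts) == 1
        assert bouts["duration"].iloc[0] == 330.0
        assert ann["asleep"].sum() == 33     # includes the first 5 min

    def test_run_below_5min_is_not_sleep(self):
        moving = np.ones(60, dtype=bool)
        moving[10:39] = False                # 290 s
        ann, bouts = score_sleep(make_annotations(moving))
        assert len(bouts) == 0
        assert not ann["asleep"].any()

    def test_interrupted_runs_are_separate_bouts(self):
        moving = np.ones(100, dtype=bool)
        moving[5:45] = False                 # 400 s
        moving[46:86] = False                # 400 s
        _, bouts = score_sleep(make_annotations(moving))
        assert len(bouts) == 2
        assert (bouts["duration"] == 400.0).all()

    def test_sleep_subset_of_immobile_and_durations_sum(self, rng):
        moving = rng.random(500) < 0.3
        ann, bouts = score_sleep(make_annotations(moving))
        assert not (ann["asleep"] & ann["moving"]).any()
        assert ann["asleep"].sum() * INTERVAL == bouts["duration"].sum()


class TestDetectDeath:
    def _ann(self, hours_immobile_at_end, total_hours=72):
        n = int(total_hours * 360)
        moving = np.tile([True, False, True, False], n // 4 + 1)[:n]
        k = int(hours_immobile_at_end * 360)
        if k:
            moving[-k:] = False
        return make_annotations(moving)

    def test_terminal_immobility_over_24h_is_death(self):
        qc = detect_death(self._ann(30))
        assert qc.dead and qc.death_onset is not None

    def test_moving_at_end_is_alive(self):
        qc = detect_death(self._ann(0))
        assert not qc.dead

    def test_short_terminal_immobility_is_alive(self):
        qc = detect_death(self._ann(10))
        assert not qc.dead

    def test_first_day_always_excluded(self):
        assert 0 in detect_death(self._ann(0)).excluded_days


class TestExtractFeatures:
    def _track_stub(self):
        return make_track([0.5, 0.5], fps=2.0)

    def test_always_asleep_fly(self, permissive_qc):
        moving = np.zeros(8640, dtype=bool)          # one full day, never moving
        ann, bouts = score_sleep(make_annotations(moving))
        f = extract_features(self._track_stub(), ann, bouts, permissive_qc)
        assert f.sleep_fraction_day == 1.0
        assert f.sleep_fraction_night == 1.0
        assert f.n_bouts_night == 1
        assert f.latency_longest_bout == 0.0

    def test_single_bout_starting_zt13_has_60min_latency(self, permissive_qc):
        moving = np.ones(8640, dtype=bool)
        zt13 = int(13 * 360)
        moving[zt13:zt13 + 60] = False               # 600-s bout at ZT13
        ann, bouts = score_sleep(make_annotations(moving))
        f = extract_features(self._track_stub(), ann, bouts, permissive_qc)
        assert f.latency_longest_bout == pytest.approx(60.0)
        assert f.n_bouts_night == 1
        assert f.mean_bout_length_night == pytest.approx(10.0)

    def test_no_retained_days_raises(self):
        moving = np.ones(8640, dtype=bool)
        ann, bouts = score_sleep(make_annotations(moving))
        qc = ethogram.QCResult("f0", dead=False, excluded_days=[0])
        with pytest.raises(ValueError):
            extract_features(self._track_stub(), ann, bouts, qc)


class TestMorningAnticipation:
    def test_uniform_activity_is_half(self):
        moving = np.tile([True, False], 4320)        # constant density all day
        assert morning_anticipation(make_annotations(moving)) == pytest.approx(0.5)

    def test_all_activity_in_final_3h(self):
        moving = np.zeros(8640, dtype=bool)
        moving[int(21 * 360):] = True
        assert morning_anticipation(make_annotations(moving)) == pytest.approx(1.0)

    def test_linear_ramp_gives_three_quarters(self, rng):
        # activity probability rises linearly from 0 at ZT18 to 1 at ZT24
        moving = np.zeros(8640, dtype=bool)
        idx = np.arange(int(18 * 360), 8640)
        p = (idx - idx[0]) / (idx[-1] - idx[0])
        moving[idx] = rng.random(idx.size) < p
        assert morning_anticipation(make_annotations(moving)) == pytest.approx(0.75, abs=0.02)

    def test_no_activity_is_missing(self):
        moving = np.zeros(8640, dtype=bool)
        moving[:360] = True                          # only morning activity
        assert math.isnan(morning_anticipation(make_annotations(moving)))
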