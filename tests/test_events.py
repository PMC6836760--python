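import numpy as np
import pytest

from quieteye import (
    DetectionParams,
    classify_trial,
    detect_fixations,
    detect_saccades,
    label_event_locations,
)
from conftest import PERIOD, make_recording
from oracles import brute_force_fixations, random_gaze_stream


def jitter(rng, n, scale=0.1):
    return rng.normal(0, scale, size=n)


class TestFixationDetection:
    def test_steady_dwell_is_one_fixation(self, params):
        rng = np.random.default_rng(0)
        rec = make_recording(2.0 + jitter(rng, 10), -1.0 + jitter(rng, 10))
        fix = detect_fixations(rec, params)
        assert len(fix) == 1
        f = fix[0]
        # half-open convention: 10 samples last 10 frame periods
        assert f.onset_ms == 0.0
        assert f.duration_ms == pytest.approx(10 * PERIOD)
        assert f.centroid == pytest.approx((2.0, -1.0), abs=0.2)
        assert f.dispersion_deg <= params.dispersion_threshold_deg

    def test_three_frames_is_the_minimum(self, params):
        # 2 in-threshold samples then a jump: 67 ms dwell, below 100 ms
        rec = make_recording([0, 0, 5, 5.1, 9, 9.3], [0, 0, 5, 5.2, 9, 9.1])
        fix = detect_fixations(rec, params)
        assert all(f.duration_ms >= 100.0 - 1e-6 for f in fix)
        assert not any(f.onset_ms == 0.0 for f in fix)
        # 3 samples dwell exactly 100 ms and qualify
        rec3 = make_recording([0, 0, 0, 5, 9, 13], [0] * 6)
        fix3 = detect_fixations(rec3, params)
        assert len(fix3) == 1 and fix3[0].duration_ms == pytest.approx(100.0)

    def test_short_deviation_is_bridged(self, params):
        # 2-frame (~67 ms) excursion mid-dwell does not split the fixation
        x = [0, 0, 0, 0, 4, 4, 0, 0, 0, 0]
        rec = make_recording(x, [0] * len(x))
        fix = detect_fixations(rec, params)
        assert len(fix) == 1
        assert fix[0].duration_ms == pytest.approx(10 * PERIOD)

    def test_long_deviation_terminates(self, params):
        # a 3-frame (100 ms) excursion ends the first fixation; the
        # excursion itself dwells long enough to count as its own fixation
        x = [0, 0, 0, 0, 4, 4, 4, 0, 0, 0, 0]
        rec = make_recording(x, [0] * len(x))
        fix = detect_fixations(rec, params)
        assert [f.onset_ms for f in fix] == pytest.approx(
            [0.0, 4 * PERIOD, 7 * PERIOD]
        )
        assert fix[0].offset_ms == pytest.approx(4 * PERIOD)

    def test_blink_gap_policy(self, params):
        # a <=100 ms invalid stretch (2 frames: next valid sample 100 ms
        # after the last accepted one) is bridged; a longer one terminates
        x = [0.0] * 12
        valid_short = [True] * 4 + [False] * 2 + [True] * 6
        rec = make_recording(x, x, valid=valid_short)
        assert len(detect_fixations(rec, params)) == 1
        valid_long = [True] * 4 + [False] * 4 + [True] * 4
        rec2 = make_recording(x, x, valid=valid_long)
        fix = detect_fixations(rec2, params)
        assert len(fix) == 2

    def test_all_invalid_warns_and_returns_empty(self, params):
        rec = make_recording([0.0] * 5, [0.0] * 5, valid=[False] * 5)
        with pytest.warns(UserWarning):
            assert detect_fixations(rec, params) == []

    def test_determinism(self, params):
        rng = np.random.default_rng(9)
        t, x, y, valid = random_gaze_stream(rng)
        rec = make_recording(x, y, valid=valid)
        a = detect_fixations(rec, params)
        b = detect_fixations(rec, params)
        assert [(f.onset_ms, f.offset_ms, f.centroid) for f in a] == [
            (f.onset_ms, f.offset_ms, f.centroid) for f in b
        ]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, params, seed):
        rng = np.random.default_rng(1000 + seed)
        for _ in range(8):
            t, x, y, valid = random_gaze_stream(rng)
            rec = make_recording(x, y, valid=valid)
            got = [(f.onset_ms, f.offset_ms) for f in detect_fixations(rec, params)]
            expected = [
                (onset, offset)
                for onset, offset, _ in brute_force_fixations(t, x, y, valid)
            ]
            assert got == pytest.approx(expected)

    def test_total_fixation_time_monotone_in_threshold(self):
        rng = np.random.default_rng(77)
        for _ in range(15):
            t, x, y, valid = random_gaze_stream(rng)
            rec = make_recording(x, y, valid=valid)
            totals = []
            for thr in (0.6, 1.25, 2.5, 5.0):
                fix = detect_fixations(rec, DetectionParams(dispersion_threshold_deg=thr))
                totals.append(sum(f.duration_ms for f in fix))
            for a, b in zip(totals, totals[1:]):
                assert b >= a - 1e-6

    def test_partition_invariant(self, params):
        rng = np.random.default_rng(31)
        for _ in range(20):
            t, x, y, valid = random_gaze_stream(rng)
            rec = make_recording(x, y, valid=valid)
            fix = detect_fixations(rec, params)
            for a, b in zip(fix, fix[1:]):
                assert a.offset_ms <= b.onset_ms + 1e-9
            if fix:
                span = fix[-1].offset_ms - fix[0].onset_ms
                assert span <= t[-1] + PERIOD - t[0] + 1e-9


class TestSaccades:
    def test_between_two_separated_fixations(self, params):
        # two dwells 6 deg apart bridged by two fast in-flight samples
        x = [0.0] * 5 + [2.0, 4.0] + [6.0] * 5
        rec = make_recording(x, [0.0] * len(x))
        fix = detect_fixations(rec, params)
        assert len(fix) == 2
        sac = detect_saccades(rec, fix, params)
        assert len(sac) == 1
        assert sac[0].onset_ms == fix[0].offset_ms
        assert sac[0].offset_ms == fix[1].onset_ms
        assert sac[0].duration_ms == pytest.approx(2 * PERIOD)

    def test_single_fixation_no_saccade(self, params):
        rec = make_recording([0.0] * 12, [0.0] * 12)
        fix = detect_fixations(rec, params)
        assert detect_saccades(rec, fix, params) == []

    def test_small_displacement_is_not_a_saccade(self, params):
        # the two dwells end up only 0.9 deg apart: the inter-fixation
        # interval is not a change of location, so no saccade
        x = [0.0] * 5 + [4.0, 8.0, 12.0] + [0.9] * 5
        rec = make_recording(x, [0.0] * len(x))
        fix = detect_fixations(rec, params)
        assert len(fix) == 2
        assert detect_saccades(rec, fix, params) == []


class TestLabeling:
    def test_static_label(self, params, layout):
        rec = make_recording([0.05] * 6, [0.0] * 6)
        fix = label_event_locations(detect_fixations(rec, params), layout)
        assert fix[0].location == "hoop_centre"

    def test_pursuit_of_ball_labels_ball(self, params, layout):
        # gaze rides the moving ball: no scene-frame fixation, but a
        # tracking fixation in ball-relative coordinates
        n = 15
        bx = np.linspace(-10, -1, n)
        by = np.linspace(-6, -9, n)
        rec = make_recording(bx, by, ball_x_deg=bx, ball_y_deg=by)
        fix, _ = classify_trial(rec, params, layout)
        assert len(fix) == 1
        assert fix[0].tracking and fix[0].location == "ball"
        assert fix[0].duration_ms == pytest.approx(n * PERIOD)

    def test_scripted_saccade_onset_recovered(self, params, layout,
                                              small_noiseless_dataset):
        _, data = small_noiseless_dataset
        checked = 0
        for rec in data.recordings[:30]:
            gt = data.ground_truth[rec.trial_id]
            if not gt.saccades:
                continue
            fix, sac = classify_trial(rec, params, layout)
            assert sac, f"no saccade detected in {rec.trial_id}"
            assert abs(sac[0].onset_ms - gt.saccades[0]["onset_ms"]) <= PERIOD + 1e-6
            checked += 1
        assert checked > 10
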