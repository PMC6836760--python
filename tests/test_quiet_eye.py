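import numpy as np
import pytest

from quieteye import (
    DataError,
    DetectionParams,
    Fixation,
    MotorPhaseSet,
    classify_trial,
    compute_occlusion,
    extract_qe_periods,
    to_relative,
)
from conftest import PERIOD


def fx(onset, offset, location, tracking=False):
    return Fixation(onset_ms=onset, offset_ms=offset, centroid=(0.0, 0.0),
                    dispersion_deg=0.2, location=location, tracking=tracking,
                    trial_id="t1")


@pytest.fixture()
def phases():
    # catch at 539, flexion 901, extension 1249, release 1397
    return MotorPhaseSet(
        arm_preparation_onset_ms=539.0,
        arm_flexion_onset_ms=901.0,
        arm_extension_onset_ms=1249.0,
        ball_release_ms=1397.0,
        trial_id="t1",
    )


class TestExtraction:
    def test_tracking_gaze_becomes_qe_catch(self, phases):
        # pursuit abandoned ~100 ms before the catch
        qe = extract_qe_periods([fx(0.0, 440.0, "ball", tracking=True)], phases)
        assert [q.phase for q in qe] == ["catch"]
        assert phases.catch_ms - qe[0].offset_ms == pytest.approx(99.0)

    def test_duplicate_across_phases_kept_for_earliest(self, phases):
        # one fixation spanning flexion and extension onsets -> flexion only
        events = [
            fx(0.0, 440.0, "ball", tracking=True),
            fx(700.0, 1300.0, "hoop_centre"),
        ]
        qe = extract_qe_periods(events, phases)
        assert [q.phase for q in qe] == ["catch", "arm_flexion"]

    def test_saccade_in_flight_means_no_arm_preparation_qe(self, phases):
        events = [fx(0.0, 440.0, "ball", tracking=True), fx(950.0, 1200.0, "net")]
        qe = extract_qe_periods(events, phases)
        assert "arm_preparation" not in [q.phase for q in qe]

    def test_ball_release_qe_must_onset_during_extension(self, phases):
        # a fixation beginning before extension onset cannot be the
        # ball-release QE even if it is the last one before release
        events = [fx(1100.0, 1396.0, "hoop_centre")]
        qe = extract_qe_periods(events, phases)
        assert [q.phase for q in qe] == ["arm_extension"]
        events2 = [fx(1250.0, 1390.0, "hoop_centre")]
        qe2 = extract_qe_periods(events2, phases)
        assert [q.phase for q in qe2] == ["ball_release"]

    def test_offset_not_clipped_to_phase_boundary(self, phases):
        qe = extract_qe_periods([fx(800.0, 1500.0, "hoop_centre")], phases)
        assert qe[0].offset_ms == 1500.0
        assert qe[0].offset_pct > 100.0

    def test_relative_times_and_location2(self, phases):
        qe = extract_qe_periods([fx(700.0, 1000.0, "net")], phases)[0]
        assert qe.onset_pct == pytest.approx(100 * 700 / 1397)
        assert qe.duration_pct == pytest.approx(100 * 300 / 1397)
        assert qe.location2 == "non_centre"
        qe2 = extract_qe_periods([fx(700.0, 1000.0, "hoop_centre")], phases)[0]
        assert qe2.location2 == "hoop_centre"

    def test_identical_onsets_rejected(self, phases):
        with pytest.raises(DataError):
            extract_qe_periods(
                [fx(700.0, 800.0, "net"), fx(700.0, 900.0, "net")], phases
            )

    def test_counts_bounded_by_fixations(self, params, layout,
                                          small_noiseless_dataset):
        _, data = small_noiseless_dataset
        total_fix = total_qe = 0
        for rec in data.recordings:
            fix, _ = classify_trial(rec, params, layout)
            qe = extract_qe_periods(fix, data.phases[rec.trial_id])
            assert len(qe) <= len(fix)
            refs = data.phases[rec.trial_id].reference_times()
            for q in qe:
                assert q.onset_ms < refs[q.phase]
            assert len({q.phase for q in qe}) == len(qe)
            total_fix += len(fix)
            total_qe += len(qe)
        assert total_qe <= total_fix

    def test_zero_noise_ground_truth_recovery(self, params, layout,
                                              small_noiseless_dataset):
        _, data = small_noiseless_dataset
        total = matched = 0
        for rec in data.recordings:
            fix, _ = classify_trial(rec, params, layout)
            qe = extract_qe_periods(fix, data.phases[rec.trial_id])
            truth = data.ground_truth[rec.trial_id].qe
            assert len(qe) == len(truth)
            total += len(truth)
            for g in truth:
                matched += any(
                    q.phase == g["phase"]
                    and q.location == g["location"]
                    and abs(q.onset_ms - g["onset_ms"]) <= PERIOD + 1e-6
                    for q in qe
                )
        assert total > 0 and matched == total


class TestRelativeTime:
    def test_midpoint(self, phases):
        assert to_relative(698.5, phases) == pytest.approx(50.0)

    def test_bounds(self, phases):
        assert to_relative(0.0, phases) == 0.0
        assert to_relative(phases.ball_release_ms, phases) == pytest.approx(100.0)

    def test_zero_duration_rejected(self):
        bad = MotorPhaseSet.__new__(MotorPhaseSet)
        bad.ball_release_ms = 0.0
        with pytest.raises(ValueError):
            to_relative(10.0, bad)


class TestOcclusion:
    def test_annotated_interval(self):
        p = MotorPhaseSet(
            arm_preparation_onset_ms=539.0, arm_flexion_onset_ms=901.0,
            arm_extension_onset_ms=1249.0, ball_release_ms=1430.9,
            occlusion_onset_ms=1174.60, occlusion_offset_ms=1469.80,
        )
        occ = compute_occlusion(p)
        assert occ.duration_ms == pytest.approx(295.2)
        # target still occluded beyond ball release (offset past 100%)
        assert occ.offset_ms - p.ball_release_ms == pytest.approx(38.9)

    def test_fully_visible_trial(self, phases):
        assert compute_occlusion(phases) is None
        t = np.arange(40) * PERIOD
        assert compute_occlusion(phases, visibility=np.ones(40, bool), t_ms=t) is None

    def test_visibility_channel(self, phases):
        t = np.arange(45) * PERIOD
        vis = np.ones(45, bool)
        vis[(t >= 1150) & (t <= 1450)] = False
        occ = compute_occlusion(phases, visibility=vis, t_ms=t)
        assert occ.onset_ms >= 1150 - PERIOD and occ.offset_ms <= 1450 + PERIOD

    def test_disjoint_intervals_pick_extension_overlap(self, phases):
        t = np.arange(45) * PERIOD
        vis = np.ones(45, bool)
        vis[2:5] = False  # early glitch
        vis[(t >= 1250) & (t <= 1400)] = False
        with pytest.warns(UserWarning):
            occ = compute_occlusion(phases, visibility=vis, t_ms=t)
        assert occ.onset_ms >= 1200.0
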