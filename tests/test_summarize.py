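import numpy as np
import pandas as pd
import pytest

from quieteye import (
    accuracy_from_trials,
    accuracy_table,
    location_probability,
    phase_share,
    qe_frequency,
    round_half_up,
    timing_summary,
)
from oracles import wilson_interval

#: Published per-participant percent accuracy across the four tests
#: (pre-test, undefended, defended, post-test).
FOUR_TESTS = pd.DataFrame(
    {
        "pre": [50, 40, 50, 30, 30, 40, 60, 50, 70, 50, 50, 60],
        "undefended": [50, 45, 45, 50, 48, 60, 83, 57, 80, 70, 52, 50],
        "defended": [40, 48, 52, 33, 48, 63, 52, 50, 48, 55, 48, 57],
        "post": [48, 64, 34, 57, 52, 57, 64, 36, 78, 72, 57, 55],
    },
    index=[f"P{i}" for i in range(1, 13)],
)


class TestAccuracy:
    def test_published_table_row_and_column_averages(self):
        out = accuracy_table(FOUR_TESTS)
        assert out.loc["P1", "4_test_average"] == 47
        assert out.loc["average", "undefended"] == 58
        assert out.loc["average", "defended"] == 50
        assert out.loc["average", "pre"] == 48
        assert out.loc["average", "post"] == 56

    def test_half_up_rounding(self):
        assert round_half_up(57.5) == 58
        assert round_half_up(49.5) == 50
        assert round_half_up(49.4999) == 49

    def test_all_hits_participant(self):
        trials = pd.DataFrame(
            {
                "participant": ["P1"] * 8,
                "condition": ["undefended"] * 4 + ["defended"] * 4,
                "outcome": ["hit"] * 8,
            }
        )
        tab = accuracy_table(accuracy_from_trials(trials))
        assert (tab.loc["P1"] == 100).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        trials = pd.DataFrame(
            {
                "participant": rng.choice(["P1", "P2"], 60),
                "condition": rng.choice(["undefended", "defended"], 60),
                "outcome": rng.choice(["hit", "miss"], 60),
            }
        )
        a = accuracy_table(accuracy_from_trials(trials))
        b = accuracy_table(accuracy_from_trials(trials.sample(frac=1, random_state=0)))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cell_warns(self):
        tab = FOUR_TESTS.astype(float).copy()
        tab.loc["P1", "pre"] = np.nan
        with pytest.warns(UserWarning):
            out = accuracy_table(tab)
        assert pd.isna(out.loc["P1", "pre"])


class TestPhaseShare:
    def test_published_counts(self):
        counts = {
            "catch": 412, "arm_preparation": 0, "arm_flexion": 322,
            "arm_extension": 165, "ball_release": 45,
        }
        share = phase_share(counts=counts)
        assert share.total_qe == 944
        got = dict(zip(share.table["phase"], share.table["pct"]))
        assert got == {
            "catch": 43.6, "arm_preparation": 0.0, "arm_flexion": 34.1,
            "arm_extension": 17.5, "ball_release": 4.8,
        }
        assert abs(share.table["pct"].sum() - 100.0) <= 0.1

    def test_equal_counts(self):
        share = phase_share(
            counts={p: 10 for p in ("catch", "arm_flexion", "arm_extension",
                                    "ball_release")}
        )
        nonzero = share.table[share.table["n_qe"] > 0]
        assert (nonzero["pct"] == 25.0).all()

    def test_share_of_fixations(self):
        share = phase_share(counts={"catch": 87}, n_fixations=100)
        assert share.qe_share_of_fixations_pct == pytest.approx(87.0)

    def test_zero_qe_warns(self):
        with pytest.warns(UserWarning):
            share = phase_share(counts={})
        assert share.total_qe == 0


class TestFrequency:
    def test_constructed_two_per_trial(self):
        trials = pd.DataFrame(
            {"trial_id": [f"t{i}" for i in range(6)], "participant": ["P1"] * 6}
        )
        qe = pd.DataFrame(
            {
                "trial_id": np.repeat([f"t{i}" for i in range(6)], 2),
                "phase": ["catch", "arm_flexion"] * 6,
            }
        )
        out = qe_frequency(qe, trials)
        assert out.loc["P1", "qe_freq_all_phases"] == pytest.approx(2.0)
        assert out.loc["P1", "qe_freq_final3"] == pytest.approx(1.0)

    def test_zero_qe_trials_do_not_divide_by_zero(self):
        trials = pd.DataFrame({"trial_id": ["a", "b"], "participant": ["P1", "P1"]})
        qe = pd.DataFrame({"trial_id": [], "phase": []})
        out = qe_frequency(qe, trials)
        assert out.loc["P1", "qe_freq_all_phases"] == 0.0

    def test_grand_mean_weighted_by_trials(self):
        # P1: 10 trials at 3 QE, P2: 2 trials at 0 QE -> weighted 2.5
        trials = pd.DataFrame(
            {
                "trial_id": [f"a{i}" for i in range(10)] + ["b0", "b1"],
                "participant": ["P1"] * 10 + ["P2"] * 2,
            }
        )
        qe = pd.DataFrame(
            {
                "trial_id": np.repeat([f"a{i}" for i in range(10)], 3),
                "phase": ["catch", "arm_flexion", "ball_release"] * 10,
            }
        )
        out = qe_frequency(qe, trials)
        assert out.loc["All", "qe_freq_all_phases"] == pytest.approx(2.5)
        unweighted = out.drop("All")["qe_freq_all_phases"].mean()
        assert out.loc["All", "qe_freq_all_phases"] > unweighted

    def test_final3_bounded_by_all_phases(self):
        rng = np.random.default_rng(8)
        ids = [f"t{i}" for i in range(40)]
        trials = pd.DataFrame(
            {"trial_id": ids, "participant": rng.choice(["P1", "P2", "P3"], 40)}
        )
        qe = pd.DataFrame(
            {
                "trial_id": rng.choice(ids, 70),
                "phase": rng.choice(
                    ["catch", "arm_flexion", "arm_extension", "ball_release"], 70
                ),
            }
        )
        out = qe_frequency(qe, trials)
        assert (out["qe_freq_final3"] <= out["qe_freq_all_phases"] + 1e-12).all()


class TestTiming:
    def test_constant_group(self):
        qe = pd.DataFrame(
            {
                "phase": ["arm_flexion"] * 3,
                "condition": ["undefended"] * 3,
                "onset_ms": [700.0] * 3,
                "offset_ms": [1000.0] * 3,
                "duration_ms": [300.0] * 3,
            }
        )
        out = timing_summary(qe)
        row = out.iloc[0]
        assert row["duration_ms_mean"] == 300.0
        assert row["duration_ms_se"] == 0.0

    def test_single_member_group_has_missing_se(self):
        qe = pd.DataFrame(
            {
                "phase": ["arm_flexion"],
                "condition": ["defended"],
                "duration_ms": [250.0],
                "onset_ms": [700.0],
                "offset_ms": [950.0],
            }
        )
        out = timing_summary(qe)
        assert np.isnan(out.iloc[0]["duration_ms_se"])

    def test_mean_consistency_identity(self):
        rng = np.random.default_rng(4)
        n = 200
        onset = rng.uniform(600, 900, n)
        dur = rng.uniform(150, 400, n)
        qe = pd.DataFrame(
            {
                "phase": rng.choice(["arm_flexion", "arm_extension"], n),
                "condition": rng.choice(["undefended", "defended"], n),
                "onset_ms": onset,
                "offset_ms": onset + dur,
                "duration_ms": dur,
            }
        )
        out = timing_summary(qe)
        for _, row in out.iterrows():
            assert row["duration_ms_mean"] == pytest.approx(
                row["offset_ms_mean"] - row["onset_ms_mean"]
            )


class TestLocationProbability:
    def test_all_centre(self):
        qe = pd.DataFrame(
            {"phase": ["arm_flexion"] * 5, "location2": ["hoop_centre"] * 5}
        )
        out = location_probability(qe)
        assert out.iloc[0]["p_hoop_centre"] == 1.0
        assert out.iloc[0]["p_non_centre"] == 0.0

    def test_proportions_sum_to_one_and_wilson_interval(self):
        qe = pd.DataFrame(
            {
                "phase": ["arm_flexion"] * 322,
                "location2": ["hoop_centre"] * 189 + ["non_centre"] * 133,
            }
        )
        out = location_probability(qe).iloc[0]
        assert out["p_hoop_centre"] + out["p_non_centre"] == pytest.approx(1.0)
        assert out["p_hoop_centre"] == pytest.approx(0.587, abs=0.001)
        lo, hi = wilson_interval(189, 322)
        assert out["ci95_low"] == pytest.approx(lo, abs=1e-9)
        assert out["ci95_high"] == pytest.approx(hi, abs=1e-9)
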