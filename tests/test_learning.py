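"""Delta-rule values, pathway-sensitivity updates, and the value race."""

import numpy as np
import pytest
from dataclasses import replace

from bgcompete import (
    DEFAULT_SCHEDULES,
    DecisionParams,
    LearningParams,
    LearningState,
    RewardSchedule,
    drift_rates,
    gains_update,
    q_update,
    run_learning_session,
    trials_to_criterion,
)
from bgcompete.learning import LearningTrace, network_race_trial, race_trial


class TestQUpdate:
    @pytest.mark.parametrize("q,r,alpha,expected", [
        (0.5, 1, 0.1, 0.55),
        (0.5, 0, 0.1, 0.45),
        (1.0, 1, 0.3, 1.0),
        (0.0, 0, 0.7, 0.0),
    ])
    def test_delta_rule(self, q, r, alpha, expected):
        assert q_update(q, r, alpha) == pytest.approx(expected)


class TestGainsUpdate:
    def test_reward_moves_chosen_gains_only(self):
        lp = LearningParams()
        s = gains_update(LearningState(), "a_opt", 1, lp)
        assert s.gains["a_opt"] == (1.0 + lp.delta, 1.0 - lp.delta)
        assert s.gains["a_sub"] == (1.0, 1.0)

    def test_nonreward_reverses_direction(self):
        lp = LearningParams()
        s = gains_update(LearningState(), "a_sub", 0, lp)
        assert s.gains["a_sub"] == (1.0 - lp.delta, 1.0 + lp.delta)

    def test_clamped_at_bounds(self):
        lp = LearningParams(gain_bounds=(0.99, 1.01))
        s = LearningState()
        for _ in range(5):
            s = gains_update(s, "a_opt", 1, lp)
        assert s.gains["a_opt"] == (1.01, 0.99)

    def test_alternating_feedback_returns_to_start(self):
        lp = LearningParams()
        s = LearningState()
        s = gains_update(s, "a_opt", 1, lp)
        s = gains_update(s, "a_opt", 0, lp)
        assert s.gains["a_opt"] == (1.0, 1.0)

    def test_rpe_scaled_step(self):
        lp = LearningParams(delta=0.1, rpe_scaled_delta=True)
        s = gains_update(LearningState(q_opt=0.75), "a_opt", 1, lp)
        # |RPE| = 0.25 -> step = 0.1 * 0.25
        assert s.gains["a_opt"][0] == pytest.approx(1.025)


class TestDriftRates:
    def test_equal_values_give_equal_drifts(self):
        lp = LearningParams(drift_base=0.1, drift_map_slope=1.0)
        assert drift_rates(LearningState(q_opt=0.4, q_sub=0.4), lp) == (0.1, 0.1)

    def test_hand_example(self):
        lp = LearningParams(drift_base=0.1, drift_map_slope=1.0)
        v = drift_rates(LearningState(q_opt=0.9, q_sub=0.5), lp)
        assert v[0] == pytest.approx(0.3)
        assert v[1] == pytest.approx(-0.1)

    def test_difference_is_odd_and_linear_in_q_diff(self):
        lp = LearningParams(drift_base=0.05, drift_map_slope=0.7)
        for qd in (-0.6, -0.2, 0.3, 0.8):
            st = LearningState(q_opt=0.5 + qd / 2, q_sub=0.5 - qd / 2)
            vo, vs = drift_rates(st, lp)
            assert vo - vs == pytest.approx(0.7 * qd)


def synthetic_trace(q_diffs) -> LearningTrace:
    records = tuple(
        {"trial": k + 1, "choice": "a_opt", "reward": 1, "rt": 500.0,
         "q_opt": 0.5 + qd / 2, "q_sub": 0.5 - qd / 2, "q_diff": qd,
         "gains_opt_d": 1.0, "gains_opt_i": 1.0,
         "gains_sub_d": 1.0, "gains_sub_i": 1.0}
        for k, qd in enumerate(q_diffs)
    )
    return LearningTrace(records=records,
                         schedule=RewardSchedule(0.8, 0.2, len(records)),
                         seed=0)


class TestTrialsToCriterion:
    def test_flat_zero_never_reaches(self):
        assert trials_to_criterion(synthetic_trace([0.0] * 50), 0.1) is None

    def test_linear_ramp_crossing(self):
        trace = synthetic_trace([0.01 * t for t in range(1, 101)])
        assert trials_to_criterion(trace, 0.5, dwell=1) == 50

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            qd = rng.uniform(-0.2, 0.9, size=60)
            trace = synthetic_trace(list(qd))
            crit, dwell = float(rng.uniform(0.1, 0.6)), int(rng.integers(1, 5))
            got = trials_to_criterion(trace, crit, dwell)
            # exhaustive scan oracle
            expected = None
            for start in range(60 - dwell + 1):
                if all(qd[start + j] >= crit for j in range(dwell)):
                    expected = start + 1
                    break
            assert got == expected


@pytest.fixture(scope="module")
def dp():
    return DecisionParams()


@pytest.fixture(scope="module")
def lp():
    return LearningParams()


class TestLearningSession:
    def test_deterministic_under_seed(self, lp, dp):
        rs = RewardSchedule(0.8, 0.2, 100)
        a = run_learning_session(rs, lp, dp, seed=4)
        b = run_learning_session(rs, lp, dp, seed=4)
        assert a.records == b.records

    def test_deterministic_reward_drives_q_diff_toward_gap(self, lp, dp):
        rs = RewardSchedule(1.0, 0.0, 600)
        finals = [run_learning_session(rs, lp, dp, seed=s).records[-1]["q_diff"]
                  for s in range(8)]
        assert np.mean(finals) > 0.9
        # trajectory is monotone non-decreasing in expectation
        qd = np.mean([run_learning_session(rs, lp, dp, seed=s).q_diffs()
                      for s in range(8)], axis=0)
        smoothed = np.convolve(qd, np.ones(25) / 25, mode="valid")
        assert np.min(np.diff(smoothed)) > -0.003

    def test_equal_schedule_is_symmetric(self, lp, dp):
        rs = RewardSchedule(0.5, 0.5, 400)
        finals = [run_learning_session(rs, lp, dp, seed=s).records[-1]["q_diff"]
                  for s in range(30)]
        assert abs(np.mean(finals)) < 0.06

    def test_preference_for_optimal_action_emerges(self, lp, dp):
        rs = DEFAULT_SCHEDULES["80/20"]
        trace = run_learning_session(rs, lp, dp, seed=11)
        ch = trace.choices()
        q1 = np.mean([c == "a_opt" for c in ch[:250]])
        q4 = np.mean([c == "a_opt" for c in ch[750:]])
        assert q4 > q1

    def test_larger_gap_learns_faster(self, lp, dp):
        meds = []
        for rs in (RewardSchedule(0.8, 0.2, 400), RewardSchedule(0.6, 0.4, 400)):
            tcs = []
            for s in range(20):
                tc = trials_to_criterion(
                    run_learning_session(rs, lp, dp, seed=100 + s), 0.15, 3)
                tcs.append(np.inf if tc is None else tc)
            meds.append(np.median(tcs))
        assert meds[0] < meds[1]

    def test_gain_difference_tracks_net_reward(self, lp, dp):
        rs = DEFAULT_SCHEDULES["80/20"]
        trace = run_learning_session(rs, lp, dp, seed=3)
        net = 0
        for r in trace.records:
            if r["choice"] == "a_opt":
                net += 1 if r["reward"] else -1
            gdiff = r["gains_opt_d"] - r["gains_opt_i"]
            if net != 0:
                assert np.sign(gdiff) == np.sign(net)


class TestRaceMechanics:
    def test_higher_drift_wins_more_often(self, lp, dp):
        wins = 0
        n = 400
        for k in range(n):
            a, _ = race_trial((0.004, 0.002), dp, lp, seed=k)
            wins += a == 0
        assert wins / n > 0.6

    def test_double_timeout_returns_none(self, lp, dp):
        lp0 = replace(lp, race_noise_sd=0.0)
        a, rt = race_trial((0.0001, 0.0001), dp, lp0, seed=0)
        assert a is None and rt is None

    def test_network_generated_choices_prefer_higher_direct_gain(self, dp):
        from bgcompete import ChannelParams, ChannelInput
        base = ChannelParams(noise_sd=0.04)
        inp = ChannelInput(I_d=0.5, I_i=0.5)
        state = LearningState(gains={"a_opt": (1.2, 0.8), "a_sub": (0.8, 1.2)})
        wins = timeouts = 0
        n = 60
        for k in range(n):
            a, _ = network_race_trial(state, base, inp, dp, seed=k)
            if a is None:
                timeouts += 1
            else:
                wins += a == 0
        assert wins / max(n - timeouts, 1) > 0.6
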