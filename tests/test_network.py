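"""Single-channel attractor dynamics: integration, gating, fixed points."""

import numpy as np
import pytest
from dataclasses import replace

from bgcompete import (
    ChannelInput,
    ChannelParams,
    InstabilityError,
    InvalidStateError,
    StateTrajectory,
    bistable_channel,
    find_fixed_points,
    gate_time,
    ratio_input,
    simulate_channel,
    simulate_channel_batch,
    step,
    SYMMETRIC_INPUT,
)
from bgcompete.network import Activation, _rhs

from conftest import make_ramp_trajectory


class TestStep:
    def test_origin_is_fixed_point_of_leak_only_dynamics(self):
        p = ChannelParams(noise_sd=0.0)
        assert step(0.0, 0.0, p, ChannelInput()) == (0.0, 0.0)

    def test_swap_symmetry_single_step(self):
        p = ChannelParams(noise_sd=0.0, g_d=1.3, g_i=1.3)
        out = step(0.4, 0.4, p, ChannelInput(I_d=0.2, I_i=0.2))
        assert out[0] == out[1]

    def test_hand_evaluated_update(self):
        # tau=100, dt=1: d' = 0.5 + 0.01*(-0.5 + f(0.2*0.5 - 0.1*0.5 + 0.3))
        p = ChannelParams(tau=100, w_self=0.2, w_inh=0.1, noise_sd=0.0, dt=1.0)
        d, i = step(0.5, 0.5, p, ChannelInput(I_d=0.3, I_i=0.1))
        assert d == pytest.approx(0.4985, abs=1e-12)
        assert i == pytest.approx(0.4965, abs=1e-12)

    def test_rectification_and_noise_scaling(self):
        p = ChannelParams(noise_sd=1.0, dt=4.0, tau=100.0)
        d, i = step(0.0, 0.0, p, ChannelInput(), noise_pair=(-5.0, 1.0))
        assert d == 0.0  # rectified
        assert i == pytest.approx(2.0)  # 1.0 * sqrt(4)

    def test_non_finite_state_rejected(self):
        p = ChannelParams(noise_sd=0.0)
        with pytest.raises(InvalidStateError):
            step(np.nan, 0.0, p, ChannelInput())

    def test_full_trajectory_swap_symmetry_under_matched_noise(self):
        p = ChannelParams(g_d=1.4, g_i=0.7, noise_sd=0.05)
        inp = ChannelInput(I_d=0.7, I_i=0.3, I_m=0.1)
        rng = np.random.default_rng(11)
        noise = rng.standard_normal((300, 2))
        d, i = 0.0, 0.0
        dm, im = 0.0, 0.0
        ps, inps = p.swapped(), inp.swapped()
        for k in range(300):
            d, i = step(d, i, p, inp, noise[k])
            # mirrored system: its direct population plays the indirect role,
            # so it receives the matched (swapped) noise draws
            dm, im = step(dm, im, ps, inps, (noise[k, 1], noise[k, 0]))
            assert d == im and i == dm


class TestSimulateChannel:
    def test_symmetric_input_gives_identical_pathways(self, quiet_params):
        traj = simulate_channel(quiet_params, SYMMETRIC_INPUT, 1000, seed=1)
        assert np.array_equal(traj.d_rate, traj.i_rate)

    def test_sample_count_includes_t0(self, quiet_params):
        traj = simulate_channel(quiet_params, SYMMETRIC_INPUT, 500, seed=0)
        assert len(traj) == 501
        assert traj.times[0] == 0.0

    def test_same_seed_bit_identical(self):
        p = ChannelParams(noise_sd=0.05)
        a = simulate_channel(p, ratio_input(2.0), 400, seed=7)
        b = simulate_channel(p, ratio_input(2.0), 400, seed=7)
        assert np.array_equal(a.d_rate, b.d_rate)
        assert np.array_equal(a.i_rate, b.i_rate)

    def test_batch_matches_individual_runs(self):
        p = ChannelParams(noise_sd=0.05)
        seeds = [3, 14, 159]
        t, d, i = simulate_channel_batch(p, ratio_input(1.7), 300, seeds)
        for k, s in enumerate(seeds):
            solo = simulate_channel(p, ratio_input(1.7), 300, seed=s)
            assert np.array_equal(d[k], solo.d_rate)
            assert np.array_equal(i[k], solo.i_rate)

    def test_higher_ratio_diverges_earlier(self, quiet_params):
        sep_times = []
        for r in (1.2, 2.0, 4.0):
            traj = simulate_channel(quiet_params, ratio_input(r), 1200, seed=0)
            sep_times.append(gate_time(traj, separation=0.5))
        assert all(t is not None for t in sep_times)
        assert sep_times[0] > sep_times[1] > sep_times[2]

    def test_modulatory_input_lifts_baseline_of_both_pathways(self, quiet_params):
        inp = ratio_input(1.5)
        lo = simulate_channel(quiet_params, inp, 300, seed=0)
        hi = simulate_channel(quiet_params, replace(inp, I_m=0.3), 300, seed=0)
        k = 150  # early epoch
        assert hi.d_rate[k] > lo.d_rate[k]
        assert hi.i_rate[k] > lo.i_rate[k]

    def test_noise_free_monotonicity_of_terminal_difference(self, quiet_params):
        diffs = []
        for r in (1.0, 1.3, 1.8, 2.5, 4.0):
            traj = simulate_channel(quiet_params, ratio_input(r), 1500, seed=0)
            diffs.append(traj.d_rate[-1] - traj.i_rate[-1])
        assert all(b >= a for a, b in zip(diffs, diffs[1:]))

    def test_divergent_dynamics_raise_named_instability(self):
        p = ChannelParams(w_self=1.6, noise_sd=0.0)
        with pytest.raises(InstabilityError) as err:
            simulate_channel(p, ChannelInput(I_d=2.0, I_i=2.0), 3000, seed=0)
        assert err.value.time_ms > 0

    def test_integration_order_dt_refinement(self, quiet_params):
        inp = ratio_input(2.0)
        coarse = simulate_channel(quiet_params, inp, 800, seed=0)
        fine = simulate_channel(replace(quiet_params, dt=0.1), inp, 800, seed=0)
        assert np.max(np.abs(coarse.d_rate - fine.d_rate[::10])) < 0.01
        assert np.max(np.abs(coarse.i_rate - fine.i_rate[::10])) < 0.01


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"tau": 0.0}, {"dt": 0.0}, {"dt": 20.0}, {"noise_sd": -1.0},
        {"w_self": -0.1}, {"g_d": 0.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ChannelParams(**kwargs)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ChannelInput(I_d=-0.1)

    def test_logistic_activation_is_bounded(self):
        f = Activation(kind="logistic", slope=2.0, offset=0.5, fmax=3.0)
        u = np.linspace(-10, 10, 101)
        assert np.all(f(u) > 0) and np.all(f(u) < 3.0)


class TestGateTime:
    def test_symmetric_trajectory_never_gates(self, quiet_params):
        traj = simulate_channel(quiet_params, SYMMETRIC_INPUT, 1000, seed=0)
        assert gate_time(traj, separation=0.05) is None

    def test_linear_ramp_crossing(self):
        traj = make_ramp_trajectory(slope=0.002)
        # |d - i| = 0.002 t >= 0.5  =>  t = 250 ms
        assert gate_time(traj, separation=0.5) == pytest.approx(250.0)

    def test_transient_crossing_rejected_by_dwell(self):
        times = np.arange(0.0, 300.0, 1.0)
        d = np.full_like(times, 1.0)
        d[50:60] = 2.0  # 10 ms blip
        traj = StateTrajectory(times=times, d_rate=d,
                               i_rate=np.full_like(times, 1.0))
        assert gate_time(traj, separation=0.5, dwell_ms=50) is None
        assert gate_time(traj, separation=0.5, dwell_ms=5) == pytest.approx(50.0)


def forward_integration_attractors(params, inp, grid_n=9, horizon=6000.0):
    """Independent oracle: integrate zero-noise dynamics from a dense grid of
    initial conditions and cluster the endpoints."""
    p0 = replace(params, noise_sd=0.0)
    ends = []
    for d0 in np.linspace(0, 5, grid_n):
        for i0 in np.linspace(0, 5, grid_n):
            t, d, i = simulate_channel_batch(p0, inp, horizon, [0], d0=d0, i0=i0)
            ends.append((d[0, -1], i[0, -1]))
    uniq = []
    for e in ends:
        if not any(abs(e[0] - u[0]) + abs(e[1] - u[1]) < 1e-3 for u in uniq):
            uniq.append(e)
    return uniq


class TestFixedPoints:
    def test_leak_dominated_regime_has_single_origin_attractor(self):
        p = ChannelParams(w_self=0.3, w_inh=0.2, noise_sd=0.0)
        fps = find_fixed_points(p, ChannelInput())
        assert len(fps.points) == 1
        (fp,) = fps.points
        assert (fp.d, fp.i) == (0.0, 0.0)
        assert fp.stability == "stable"

    def test_bistable_regime_two_stable_one_saddle(self):
        p = bistable_channel(noise_sd=0.0)
        fps = find_fixed_points(p, SYMMETRIC_INPUT)
        assert len(fps.stable) == 2
        assert len(fps.saddles) == 1
        # closed-form check: winner at c/(1-w_self), saddle at c/(1-w_self+w_inh)
        go = max(fps.stable, key=lambda q: q.d)
        assert go.d == pytest.approx(0.5 / (1 - 0.8), rel=1e-6)
        assert go.i == pytest.approx(0.0, abs=1e-9)
        assert fps.saddles[0].d == pytest.approx(0.5 / 0.7, rel=1e-6)

    def test_point_set_closed_under_swap_for_symmetric_problem(self):
        p = bistable_channel(noise_sd=0.0)
        fps = find_fixed_points(p, SYMMETRIC_INPUT)
        pts = {(round(q.d, 8), round(q.i, 8)) for q in fps.points}
        assert pts == {(i, d) for d, i in pts}

    def test_stable_points_match_forward_integration_oracle(self):
        p = bistable_channel(noise_sd=0.0)
        attractors = forward_integration_attractors(p, SYMMETRIC_INPUT)
        fps = find_fixed_points(p, SYMMETRIC_INPUT)
        stable = [(q.d, q.i) for q in fps.stable]
        # every oracle attractor coincides with a reported stable point
        matched = 0
        for a in attractors:
            if any(abs(a[0] - s[0]) < 1e-2 and abs(a[1] - s[1]) < 1e-2
                   for s in stable):
                matched += 1
        assert matched >= 2
        # all residuals vanish at reported equilibria
        for q in fps.points:
            assert np.abs(_rhs(np.array([q.d, q.i]), p, SYMMETRIC_INPUT)).max() < 1e-9

    def test_noise_reaches_both_attractors(self):
        p = bistable_channel(noise_sd=0.04)
        t, d, i = simulate_channel_batch(p, SYMMETRIC_INPUT, 1500,
                                         list(range(200)))
        diff = d[:, -1] - i[:, -1]
        assert (diff > 1.0).mean() >= 0.05
        assert (diff < -1.0).mean() >= 0.05
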