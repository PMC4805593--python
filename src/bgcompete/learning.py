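"""Reinforcement layer: probabilistic selection with dopamine-like updates.

An agent repeatedly chooses between two stimuli with unequal reward
probabilities (p_opt >= p_sub).  Each choice is produced by a race between
two stochastic constant-drift accumulators, one per action, whose drift
rates are tied to the learned action values:

    drift_opt = drift_base + slope * (Q_opt - Q_sub) / 2
    drift_sub = drift_base - slope * (Q_opt - Q_sub) / 2

so equal values give equal drifts and the value difference alone separates
them.  After feedback, the chosen action's value is updated by the delta
rule on the reward-prediction error, Q <- Q + alpha * (r - Q), and the
chosen action's pathway sensitivities receive the phasic-dopamine update:
+delta to the direct and -delta to the indirect sensitivity after reward,
and the reverse after non-reward (clamped to configured bounds).

Exploration is not a separate policy parameter: accumulator noise alone
decides whether the currently lower-valued action is sampled, so behaviour
shifts from exploratory to exploitative as the value gap widens.  The
pathway-sensitivity (gain) layer is carried alongside the abstract Q/drift
layer so the full network simulation can generate choices from learned
gains when desired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .decision import DecisionParams
from .network import ChannelInput, ChannelParams, simulate_channel_batch
from .decision import evidence_from_rates
from .seeds import derive_seed

__all__ = [
    "RewardSchedule",
    "LearningParams",
    "LearningState",
    "LearningTrace",
    "DEFAULT_SCHEDULES",
    "q_update",
    "gains_update",
    "drift_rates",
    "race_trial",
    "run_learning_session",
    "trials_to_criterion",
]

ACTIONS = ("a_opt", "a_sub")


@dataclass(frozen=True)
class RewardSchedule:
    """Bernoulli reward probabilities of the optimal and suboptimal stimulus."""

    p_opt: float
    p_sub: float
    n_trials: int = 1000

    def __post_init__(self):
        if not (0.0 <= self.p_sub <= self.p_opt <= 1.0):
            raise ValueError("require 0 <= p_sub <= p_opt <= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


# Probabilistic-selection presets: large / medium / small probability gap.
DEFAULT_SCHEDULES = {
    "80/20": RewardSchedule(0.80, 0.20),
    "70/30": RewardSchedule(0.70, 0.30),
    "60/40": RewardSchedule(0.60, 0.40),
}


@dataclass(frozen=True)
class LearningParams:
    """Learning and choice parameters.

    alpha_q        : value learning rate in (0, 1].
    delta          : pathway-sensitivity increment per feedback event (> 0).
    drift_map_slope: scale from value difference to drift-rate difference
                     (evidence/ms per unit Q-difference).
    drift_base     : drift shared by both actions at Q-equality (evidence/ms).
    gain_bounds    : clamp interval for pathway sensitivities.
    rpe_scaled_delta : if True, the sensitivity increment is delta * |RPE|
                     instead of the fixed +/-delta.
    race_noise_sd  : accumulator noise SD (evidence / sqrt(ms)).
    race_dt        : accumulator integration step, ms.
    """

    alpha_q: float = 0.05
    delta: float = 0.01
    drift_map_slope: float = 0.003
    drift_base: float = 0.0025
    gain_bounds: tuple = (0.2, 3.0)
    rpe_scaled_delta: bool = False
    race_noise_sd: float = 0.05
    race_dt: float = 5.0

    def __post_init__(self):
        if not (0.0 < self.alpha_q <= 1.0):
            raise ValueError("alpha_q must be in (0, 1]")
        if not self.delta > 0:
            raise ValueError("delta must be > 0")
        lo, hi = self.gain_bounds
        if not lo < hi:
            raise ValueError("gain_bounds must be well-ordered")
        if self.race_noise_sd < 0 or self.race_dt <= 0:
            raise ValueError("invalid race noise/step")


@dataclass(frozen=True)
class LearningState:
    """Current action values and pathway sensitivities."""

    q_opt: float = 0.5
    q_sub: float = 0.5
    gains: dict = field(default_factory=lambda: {
        "a_opt": (1.0, 1.0), "a_sub": (1.0, 1.0)})
    trial_index: int = 0

    def __post_init__(self):
        for q in (self.q_opt, self.q_sub):
            if not (0.0 <= q <= 1.0):
                raise ValueError("q values must be in [0, 1]")

    @property
    def q_diff(self) -> float:
        return self.q_opt - self.q_sub


@dataclass(frozen=True)
class LearningTrace:
    """Per-trial history of one learning session."""

    records: tuple  # dicts: trial, choice, reward, rt, q_opt, q_sub, q_diff, gains
    schedule: RewardSchedule
    seed: int

    def q_diffs(self) -> np.ndarray:
        return np.array([r["q_diff"] for r in self.records])

    def choices(self) -> list:
        return [r["choice"] for r in self.records]


def q_update(q: float, reward: int, alpha_q: float) -> float:
    """Delta rule on the reward-prediction error; stays in [0, 1]."""
    return q + alpha_q * (reward - q)


def gains_update(state: LearningState, chosen: str, reward: int,
                 lp: LearningParams, rpe: Optional[float] = None) -> LearningState:
    """Phasic-dopamine update of the chosen action's pathway sensitivities.

    Reward: direct sensitivity +delta, indirect -delta; non-reward: the
    reverse.  With ``rpe_scaled_delta`` the step is delta * |rpe|.  The
    unchosen action is untouched; results are clamped to gain_bounds.
    """
    if chosen not in ACTIONS:
        raise ValueError(f"chosen must be one of {ACTIONS}")
    step = lp.delta
    if lp.rpe_scaled_delta:
        if rpe is None:
            q = state.q_opt if chosen == "a_opt" else state.q_sub
            rpe = reward - q
        step = lp.delta * abs(rpe)
    sign = 1.0 if reward else -1.0
    lo, hi = lp.gain_bounds
    g_d, g_i = state.gains[chosen]
    new = (min(max(g_d + sign * step, lo), hi),
           min(max(g_i - sign * step, lo), hi))
    gains = dict(state.gains)
    gains[chosen] = new
    return replace(state, gains=gains)


def drift_rates(state: LearningState, lp: LearningParams) -> tuple:
    """Value-proportional drift rates (drift_opt, drift_sub)."""
    half = lp.drift_map_slope * state.q_diff / 2.0
    return lp.drift_base + half, lp.drift_base - half


def race_trial(drifts: tuple, dp: DecisionParams, lp: LearningParams,
               seed: int) -> tuple:
    """Race two constant-drift diffusions to threshold.

    Each accumulator follows X(t) = v t + sigma W(t); the first to reach
    the execution threshold within the deadline wins.  Returns
    (choice index or None, rt ms or None).  A double timeout returns
    (None, None) for the caller's forced-guess rule.
    """
    rng = np.random.default_rng(seed)
    horizon = dp.deadline - dp.t0
    n_steps = int(np.ceil(horizon / lp.race_dt - 1e-9))
    t = np.arange(1, n_steps + 1) * lp.race_dt
    noise = rng.standard_normal((2, n_steps))
    paths = (np.asarray(drifts)[:, None] * t[None, :]
             + lp.race_noise_sd * np.sqrt(lp.race_dt) * np.cumsum(noise, axis=1))
    hit = paths >= dp.threshold
    t_cross = [float(t[int(np.argmax(hit[a]))]) if hit[a].any() else np.inf
               for a in range(2)]
    if np.isinf(min(t_cross)):
        return None, None
    if t_cross[0] == t_cross[1]:
        a = int(rng.integers(2))
    else:
        a = int(np.argmin(t_cross))
    return a, dp.t0 + t_cross[a]


def run_learning_session(rs: RewardSchedule, lp: LearningParams,
                         dp: DecisionParams, seed: int,
                         state: Optional[LearningState] = None) -> LearningTrace:
    """One probabilistic-selection session of rs.n_trials trials.

    Per trial: drifts from the current state, choice from the accumulator
    race (double timeouts fall back to an unbiased forced guess, which is
    still rewarded and learned from), Bernoulli reward of the chosen
    stimulus, then delta-rule and sensitivity updates of the chosen action
    only.  Fully reproducible from the seed.
    """
    if state is None:
        state = LearningState()
    reward_rng = np.random.default_rng(derive_seed(seed, "reward"))
    guess_rng = np.random.default_rng(derive_seed(seed, "guess"))
    records = []
    for k in range(rs.n_trials):
        drifts = drift_rates(state, lp)
        a, rt = race_trial(drifts, dp, lp, derive_seed(seed, "race", k))
        if a is None:
            a = int(guess_rng.integers(2))
        choice = ACTIONS[a]
        p = rs.p_opt if choice == "a_opt" else rs.p_sub
        reward = int(reward_rng.random() < p)
        q = state.q_opt if choice == "a_opt" else state.q_sub
        rpe = reward - q
        state = gains_update(state, choice, reward, lp, rpe=rpe)
        q_new = q_update(q, reward, lp.alpha_q)
        if choice == "a_opt":
            state = replace(state, q_opt=q_new, trial_index=k + 1)
        else:
            state = replace(state, q_sub=q_new, trial_index=k + 1)
        records.append({
            "trial": k + 1, "choice": choice, "reward": reward, "rt": rt,
            "q_opt": state.q_opt, "q_sub": state.q_sub,
            "q_diff": state.q_diff,
            "gains_opt_d": state.gains["a_opt"][0],
            "gains_opt_i": state.gains["a_opt"][1],
            "gains_sub_d": state.gains["a_sub"][0],
            "gains_sub_i": state.gains["a_sub"][1],
        })
    return LearningTrace(records=tuple(records), schedule=rs, seed=seed)


def trials_to_criterion(trace: LearningTrace, criterion: float,
                        dwell: int = 1) -> Optional[int]:
    """First trial number from which q_diff >= criterion for ``dwell``
    consecutive trials; None if never reached."""
    if criterion <= 0:
        raise ValueError("criterion must be > 0")
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    qd = trace.q_diffs()
    ok = qd >= criterion
    run = 0
    for k, flag in enumerate(ok):
        run = run + 1 if flag else 0
        if run >= dwell:
            return int(trace.records[k - dwell + 1]["trial"])
    return None


def network_race_trial(state: LearningState, base_params: ChannelParams,
                       base_input: ChannelInput, dp: DecisionParams,
                       seed: int) -> tuple:
    """Choice from the full network competition, using learned gains.

    Each action's channel uses its learned (direct, indirect) sensitivities
    as the pathway gains g_d / g_i; the two channels' evidence traces race
    to threshold as in the cued task.  Returns (choice index or None, rt).
    """
    horizon = dp.deadline - dp.t0
    crossings = []
    for a, action in enumerate(ACTIONS):
        g_d, g_i = state.gains[action]
        params = replace(base_params, g_d=g_d, g_i=g_i)
        t, d, i = simulate_channel_batch(
            params, base_input, horizon, [derive_seed(seed, f"action:{a}")])
        ev = evidence_from_rates(t, d, i, dp)[0]
        window = t <= dp.deadline - dp.t0 + 1e-9
        hit = (ev >= dp.threshold) & window
        crossings.append(float(t[int(np.argmax(hit))]) if hit.any() else np.inf)
    if np.isinf(min(crossings)):
        return None, None
    if crossings[0] == crossings[1]:
        a = int(np.random.default_rng(derive_seed(seed, "tie")).integers(2))
    else:
        a = int(np.argmin(crossings))
    return a, dp.t0 + crossings[a]
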