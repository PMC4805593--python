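"""Tonic-dopamine sweeps: background drive trades exploration for exploitation.

Tonic dopamine is modelled as the non-specific background drive I_lambda
reaching both populations of every channel.  With the cortical input ratio
to the direct vs indirect pathway held fixed, raising I_lambda lifts the
network's operating point above the activation threshold of its transfer
function: separation of the pathways starts sooner and is driven by the
mean dynamics rather than by rare noise excursions, so decisions get
faster and less variable trial-to-trial (exploitation).  At low I_lambda
the network idles near rest and commitment depends on noise, producing
slow, variable, more exploratory behaviour.

The same lever is applied to the value-based race by adding a tonic
component to the shared drift base; choice entropy of the race under fixed
unequal action values quantifies exploration in bits.

Tonic modulation changes expression only: sweeps never touch learned gains
or values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .decision import DecisionParams, TrialOutcome, TrialSet, run_trials, summarize
from .learning import LearningParams, LearningState, race_trial
from .network import (
    ChannelInput,
    ChannelParams,
    InstabilityError,
    StateTrajectory,
    gate_time,
)
from .seeds import derive_seed

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_tonic_sweep",
    "choice_entropy",
    "race_choice_set",
]


@dataclass(frozen=True)
class SweepSpec:
    """Specification of a tonic background-drive sweep.

    levels          : strictly increasing I_lambda values.
    n_per_level     : go/no-go trials per level.
    base_params     : channel constants (shared across levels).
    base_input      : drive template; its I_d:I_i ratio is held fixed while
                      I_lambda is overwritten per level.
    decision_params : accumulator readout.
    gate_separation : rate-difference criterion for the gate-time statistic.
    learning_params / probe_q_diff / tonic_drift_gain / n_entropy_trials :
                      configuration of the value-race entropy probe run at
                      each level with fixed unequal Q values; tonic drive
                      scales both accumulators' drifts by the excitability
                      factor (1 + tonic_drift_gain * I_lambda), so higher
                      background drive yields faster and more reliable
                      expression of the same value difference.
    """

    levels: tuple = (0.2, 0.7, 1.2)
    n_per_level: int = 1000
    base_params: ChannelParams = None
    base_input: ChannelInput = None
    decision_params: DecisionParams = None
    gate_separation: float = 0.1
    learning_params: LearningParams = None
    probe_q_diff: float = 0.4
    tonic_drift_gain: float = 2.0
    n_entropy_trials: int = 1000
    seed: int = 0

    def __post_init__(self):
        lv = tuple(float(x) for x in self.levels)
        if len(lv) < 1 or not all(b > a for a, b in zip(lv, lv[1:])):
            raise ValueError("levels must be strictly increasing")
        object.__setattr__(self, "levels", lv)
        if self.n_per_level < 1:
            raise ValueError("n_per_level must be >= 1")
        if self.base_params is None:
            # stronger cortical weighting of the direct pathway; operating
            # point below the activation offset at low background drive so
            # commitment at low I_lambda is a noise-driven escape
            from .network import Activation
            object.__setattr__(self, "base_params", ChannelParams(
                w_self=0.7, g_d=1.2, g_i=0.8, noise_sd=0.06,
                activation=Activation(offset=0.6)))
        if self.base_input is None:
            # equal cortical input to both pathways; the asymmetry comes
            # from the gains, and the background drive shares them
            object.__setattr__(self, "base_input", ChannelInput(
                I_d=0.5, I_i=0.5, gain_nonselective=True))
        if self.decision_params is None:
            object.__setattr__(self, "decision_params",
                               DecisionParams(threshold=2.0, deadline=2500.0))
        if self.learning_params is None:
            object.__setattr__(self, "learning_params", LearningParams())


@dataclass(frozen=True)
class SweepResult:
    levels: tuple
    records: tuple  # one summary dict per level
    trial_sets: tuple  # archived TrialSets, one per level

    def series(self, key: str) -> list:
        return [r[key] for r in self.records]


def choice_entropy(ts: TrialSet) -> float:
    """Shannon entropy (bits) of the empirical response distribution.

    0*log0 contributes 0; an empty trial set has no defined entropy.
    """
    if ts.n == 0:
        raise ValueError("entropy undefined for an empty trial set")
    labels = ts.labels()
    counts = np.array([labels.count(l) for l in sorted(set(labels))], float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p, where=p > 0, out=np.zeros_like(p))).sum())


def race_choice_set(lp: LearningParams, dp: DecisionParams, q_diff: float,
                    n: int, seed: int) -> TrialSet:
    """Choices of the value race at a frozen Q difference (no learning)."""
    state = LearningState(q_opt=0.5 + q_diff / 2.0, q_sub=0.5 - q_diff / 2.0)
    from .learning import drift_rates, ACTIONS
    drifts = drift_rates(state, lp)
    guess_rng = np.random.default_rng(derive_seed(seed, "guess"))
    outcomes = []
    for k in range(n):
        a, rt = race_trial(drifts, dp, lp, derive_seed(seed, "race", k))
        if a is None:
            a = int(guess_rng.integers(2))
            outcomes.append(TrialOutcome(ACTIONS[a], None, False, "timeout"))
        else:
            outcomes.append(TrialOutcome(ACTIONS[a], rt, True))
    return TrialSet(outcomes=tuple(outcomes), n=n, base_seed=seed)


def run_tonic_sweep(spec: SweepSpec) -> SweepResult:
    """Go/no-go statistics and race entropy at each background-drive level.

    Each level runs ``n_per_level`` trials through the decision readout
    with I_lambda set on the otherwise fixed drive template, then an
    entropy probe of the value race with the level's tonic drift.  Learned
    state is never modified.  Reproducible from spec.seed; identical levels
    with identical derived seeds give identical records.
    """
    records = []
    sets = []
    for j, lam in enumerate(spec.levels):
        inp = replace(spec.base_input, I_lambda=lam)
        level_seed = derive_seed(spec.seed, f"level:{lam!r}")
        try:
            ts = run_trials(spec.base_params, inp, spec.decision_params,
                            spec.n_per_level, level_seed,
                            condition=f"I_lambda={lam}")
        except InstabilityError as exc:
            raise InstabilityError(exc.time_ms, exc.value, exc.batch_index,
                                   context=f"I_lambda level {lam}") from exc
        summ = summarize(ts)
        # gate-time median over a subsample of the level's trajectories
        gate_med = _gate_time_median(spec, inp, level_seed)
        gain = 1.0 + spec.tonic_drift_gain * lam
        probe = race_choice_set(
            replace(spec.learning_params,
                    drift_base=spec.learning_params.drift_base * gain,
                    drift_map_slope=spec.learning_params.drift_map_slope * gain),
            spec.decision_params, spec.probe_q_diff, spec.n_entropy_trials,
            derive_seed(spec.seed, f"entropy:{lam!r}"),
        )
        rec = {
            "I_lambda": lam,
            "go_rate": summ["go_rate"],
            "mean_rt": summ["mean_rt"],
            "sd_rt": summ["sd_rt"],
            "rt_quantiles": summ["rt_quantiles"],
            "gate_time_median": gate_med,
            "entropy_bits": choice_entropy(probe),
        }
        records.append(rec)
        sets.append(ts)
    return SweepResult(levels=spec.levels, records=tuple(records),
                       trial_sets=tuple(sets))


def _gate_time_median(spec: SweepSpec, inp: ChannelInput, level_seed: int,
                      n_sub: int = 50) -> Optional[float]:
    from .network import simulate_channel_batch
    dp = spec.decision_params
    horizon = dp.deadline - dp.t0
    seeds = [derive_seed(level_seed, "gate", k) for k in range(n_sub)]
    t, d, i = simulate_channel_batch(spec.base_params, inp, horizon, seeds)
    gts = []
    for k in range(n_sub):
        traj = StateTrajectory(times=t, d_rate=d[k], i_rate=i[k], seed=seeds[k])
        gt = gate_time(traj, spec.gate_separation)
        if gt is not None:
            gts.append(gt)
    return float(np.median(gts)) if gts else None
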