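"""Go/no-go readout: accumulate the normalized pathway difference to threshold.

The decision variable is the running integral of the normalized difference
between the direct and indirect population rates,

    evidence(t) = sum_k  beta * (D_k - I_k) / (D_k + I_k + eps) * dt,

which is bounded in slope by +/- beta and degenerates gracefully at rest.
A "go" is emitted at the first time the evidence reaches the execution
threshold theta before the trial deadline; if the threshold is never
reached by the deadline the trial ends as "no-go".  Conceptually the
threshold is the level of pallidal disinhibition needed to release the
thalamus; here it is an abstract criterion on accumulated evidence.

Evidence may go negative during transient indirect-pathway dominance; there
is no lower absorbing bound — no-go is a deadline outcome, not a boundary
crossing.  A crossing exactly at the deadline sample counts as go (closed
right endpoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import (
    ChannelInput,
    ChannelParams,
    StateTrajectory,
    params_fingerprint,
    simulate_channel_batch,
)
from .seeds import derive_seed

__all__ = [
    "DecisionParams",
    "EvidenceTrace",
    "TrialOutcome",
    "TrialSet",
    "decision_evidence",
    "classify_trial",
    "run_trials",
    "summarize",
]

RT_QUANTILES = (0.10, 0.30, 0.50, 0.70, 0.90)


@dataclass(frozen=True)
class DecisionParams:
    """Accumulator readout parameters.

    threshold : execution threshold theta on accumulated evidence (> 0).
    deadline  : trial deadline T in ms; evidence not at threshold by
                T - t0 yields a no-go.
    evidence_gain : scale beta applied to the normalized difference (1/ms).
    norm_eps  : denominator guard epsilon (rate units, > 0).
    t0        : non-decision time added to crossing times (ms, >= 0).
    baseline  : optional starting offset of the evidence trace.
    """

    threshold: float = 2.5
    deadline: float = 1200.0
    evidence_gain: float = 0.005
    norm_eps: float = 1e-3
    t0: float = 0.0
    baseline: float = 0.0

    def __post_init__(self):
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        if not self.deadline > self.t0:
            raise ValueError("deadline must exceed t0")
        if not self.norm_eps > 0:
            raise ValueError("norm_eps must be > 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")


@dataclass(frozen=True)
class EvidenceTrace:
    times: np.ndarray
    evidence: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, float)
        e = np.asarray(self.evidence, float)
        if len(t) != len(e):
            raise ValueError("times and evidence must have equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "evidence", e)


@dataclass(frozen=True)
class TrialOutcome:
    label: str  # {"go", "no-go"} or {"left", "right", "timeout"}
    rt: Optional[float]  # ms; present iff crossed
    crossed: bool
    condition: str = ""
    seed: Optional[int] = None

    def __post_init__(self):
        if self.crossed != (self.rt is not None):
            raise ValueError("rt must be present iff the threshold was crossed")


@dataclass(frozen=True)
class TrialSet:
    outcomes: tuple
    n: int
    base_seed: Optional[int] = None
    fingerprint: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.outcomes) != self.n:
            raise ValueError("outcome count must equal n")

    def rts(self) -> np.ndarray:
        return np.array([o.rt for o in self.outcomes if o.rt is not None])

    def labels(self) -> list:
        return [o.label for o in self.outcomes]


def _normalized_difference(d, i, eps):
    return (np.asarray(d) - np.asarray(i)) / (np.asarray(d) + np.asarray(i) + eps)


def evidence_from_rates(times, d, i, dp: DecisionParams):
    """Cumulative evidence along the last axis of rate arrays d, i."""
    d = np.asarray(d, float)
    i = np.asarray(i, float)
    nd = _normalized_difference(d, i, dp.norm_eps)
    dt = np.diff(np.asarray(times, float))
    ev = np.zeros_like(nd)
    # left-endpoint rule: evidence at sample k integrates rates over [0, t_k)
    ev[..., 1:] = np.cumsum(dp.evidence_gain * nd[..., :-1] * dt, axis=-1)
    return ev + dp.baseline


def decision_evidence(traj: StateTrajectory, dp: DecisionParams) -> EvidenceTrace:
    """Accumulated normalized-difference evidence for a trajectory."""
    ev = evidence_from_rates(traj.times, traj.d_rate, traj.i_rate, dp)
    return EvidenceTrace(times=traj.times, evidence=ev)


def _first_crossing(times, evidence, dp: DecisionParams) -> Optional[float]:
    """Crossing time within the decision window, or None."""
    window = times <= dp.deadline - dp.t0 + 1e-9
    hit = (evidence >= dp.threshold) & window
    if not hit.any():
        return None
    return float(times[int(np.argmax(hit))])


def classify_trial(ev: EvidenceTrace, dp: DecisionParams,
                   condition: str = "", seed: Optional[int] = None) -> TrialOutcome:
    """Go/no-go outcome of an evidence trace under the deadline rule."""
    if ev.times[-1] < dp.deadline - dp.t0 - 1e-9:
        raise ValueError(
            f"evidence trace ends at {ev.times[-1]} ms but must cover "
            f"[0, {dp.deadline - dp.t0}] ms"
        )
    t_cross = _first_crossing(ev.times, ev.evidence, dp)
    if t_cross is None:
        return TrialOutcome("no-go", None, False, condition, seed)
    return TrialOutcome("go", dp.t0 + t_cross, True, condition, seed)


def run_trials(
    params: ChannelParams,
    inp: ChannelInput,
    dp: DecisionParams,
    n: int,
    seed: int,
    condition: str = "",
) -> TrialSet:
    """Monte-Carlo go/no-go trials of one channel.

    Trial k uses the child seed ``derive_seed(seed, "trial", k)``; the whole
    set is reproducible from the base seed, and a batch run is bit-identical
    to simulating each trial on its own.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    horizon = dp.deadline - dp.t0
    trial_seeds = [derive_seed(seed, "trial", k) for k in range(n)]
    times, d, i = simulate_channel_batch(params, inp, horizon, trial_seeds)
    ev = evidence_from_rates(times, d, i, dp)
    outcomes = []
    for k in range(n):
        outcomes.append(
            classify_trial(EvidenceTrace(times, ev[k]), dp, condition,
                           trial_seeds[k])
        )
    return TrialSet(
        outcomes=tuple(outcomes), n=n, base_seed=seed,
        fingerprint=params_fingerprint(params, inp),
        metadata={"condition": condition},
    )


def summarize(ts: TrialSet) -> dict:
    """Go-rate and RT statistics (go trials only) of a trial set.

    RT fields are None when no trial crossed threshold.
    """
    go_labels = {"go", "left", "right"}
    n_go = sum(1 for o in ts.outcomes if o.label in go_labels and o.crossed)
    rts = ts.rts()
    out = {"n": ts.n, "go_rate": n_go / ts.n}
    if len(rts) == 0:
        out.update(mean_rt=None, sd_rt=None,
                   rt_quantiles={q: None for q in RT_QUANTILES})
        return out
    out["mean_rt"] = float(np.mean(rts))
    out["sd_rt"] = float(np.std(rts, ddof=1)) if len(rts) > 1 else 0.0
    out["rt_quantiles"] = {
        q: float(np.quantile(rts, q)) for q in RT_QUANTILES
    }
    return out
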