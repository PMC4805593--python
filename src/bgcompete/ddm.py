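"""Moment-based recovery of effective drift-diffusion parameters.

Trial sets from the network or the value race are summarized by the
three-statistic closed-form inversion of the two-boundary constant-drift
diffusion (the EZ-diffusion equations of Wagenmakers, van der Maas &
Grasman, 2007, with diffusion coefficient s = 1): accuracy Pc, the mean
MRT and variance VRT of correct-response times give

    L   = log(Pc / (1 - Pc))
    v   = sign(Pc - 1/2) * [ L (L Pc^2 - L Pc + Pc - 1/2) / VRT ]^(1/4)
    a   = L / v
    t0  = MRT - (a / 2v) * (1 - exp(-v a)) / (1 + exp(-v a))

This maps condition differences produced by network manipulations onto the
accumulator-model vocabulary: a change in input ratio should surface as a
drift-rate change (faster AND more accurate), while a criterion change
would trade speed against accuracy.  The module reports effective
parameters only; it fits no likelihood and claims nothing about where in
the circuit the threshold is physically implemented.

Internally the network works in ms; conversion to seconds happens only at
this module's boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .decision import TrialSet
from .seeds import derive_seed

__all__ = [
    "DDMParams",
    "estimate_ddm",
    "estimate_from_arrays",
    "compare_conditions",
    "simulate_diffusion_trials",
]

MIN_TRIALS = 100


@dataclass(frozen=True)
class DDMParams:
    """Effective diffusion parameters: drift v (1/s), boundary separation a,
    non-decision time t0 (s), with fit metadata."""

    drift: float
    boundary: float
    t0: float
    n: int = 0
    accuracy: Optional[float] = None

    def __post_init__(self):
        if not self.boundary > 0:
            raise ValueError("boundary must be > 0")


def _edge_correct(pc: float, n: int) -> float:
    """Continuous edge rule: clamp accuracy into [1/(2n), 1 - 1/(2n)],
    and nudge an exact 0.5 (where the inversion is singular)."""
    lo = 1.0 / (2 * n)
    pc = min(max(pc, lo), 1.0 - lo)
    if pc == 0.5:
        pc += lo / 2.0
    return pc


def estimate_from_arrays(correct: np.ndarray, rt_ms: np.ndarray) -> DDMParams:
    """Closed-form inversion from trial-level correctness and RTs (ms)."""
    correct = np.asarray(correct, bool)
    rt_s = np.asarray(rt_ms, float) / 1000.0
    n = len(correct)
    if n < MIN_TRIALS:
        raise ValueError(f"need >= {MIN_TRIALS} completed trials, got {n}")
    if len(rt_s) != n:
        raise ValueError("correct and rt arrays must align")
    pc = _edge_correct(float(np.mean(correct)), n)
    rt_c = rt_s[correct] if correct.any() else rt_s
    rt_c = np.sort(rt_c)  # exact invariance to trial order
    mrt = float(np.mean(rt_c))
    vrt = float(np.var(rt_c, ddof=1)) if len(rt_c) > 1 else np.nan
    if not np.isfinite(vrt) or vrt <= 0:
        raise ValueError("correct-RT variance must be positive and finite")
    L = np.log(pc / (1.0 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / vrt
    v = float(np.sign(pc - 0.5) * x**0.25)
    a = float(L / v)
    y = -v * a
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(y)) / (1.0 + np.exp(y))
    t0 = max(mrt - float(mdt), 0.0)
    return DDMParams(drift=v, boundary=a, t0=t0, n=n, accuracy=pc)


def _completed(ts: TrialSet) -> tuple:
    correct, rts = [], []
    for o in ts.outcomes:
        if not o.crossed or o.rt is None:
            continue
        correct.append(o.condition == "correct")
        rts.append(o.rt)
    return np.array(correct, bool), np.array(rts, float)


def estimate_ddm(ts: TrialSet) -> DDMParams:
    """Effective DDM parameters of a two-alternative trial set.

    Completed outcomes must carry ``condition`` in {"correct", "error"}
    (as produced by the cued-choice block's trial-set reduction).  Invariant
    to trial order; deterministic given the set.
    """
    correct, rts = _completed(ts)
    return estimate_from_arrays(correct, rts)


def compare_conditions(a: TrialSet, b: TrialSet, n_boot: int = 1000,
                       seed: int = 0, ci: float = 0.95) -> dict:
    """Bootstrap percentile intervals on per-parameter differences (a - b).

    Trials are resampled with replacement within each set; resamples where
    the closed-form inversion is undefined are redrawn.
    """
    ca, ra = _completed(a)
    cb, rb = _completed(b)
    point_a = estimate_from_arrays(ca, ra)
    point_b = estimate_from_arrays(cb, rb)
    rng = np.random.default_rng(derive_seed(seed, "boot"))
    diffs = {"drift": [], "boundary": [], "t0": []}
    draws = 0
    while len(diffs["drift"]) < n_boot:
        draws += 1
        if draws > 20 * n_boot:
            raise RuntimeError("bootstrap failed to produce valid resamples")
        ia = rng.integers(len(ca), size=len(ca))
        ib = rng.integers(len(cb), size=len(cb))
        try:
            ea = estimate_from_arrays(ca[ia], ra[ia])
            eb = estimate_from_arrays(cb[ib], rb[ib])
        except ValueError:
            continue
        diffs["drift"].append(ea.drift - eb.drift)
        diffs["boundary"].append(ea.boundary - eb.boundary)
        diffs["t0"].append(ea.t0 - eb.t0)
    alpha = (1.0 - ci) / 2.0
    out = {}
    for key in diffs:
        arr = np.array(diffs[key])
        out[key] = {
            "difference": getattr(point_a, key) - getattr(point_b, key),
            "ci_low": float(np.quantile(arr, alpha)),
            "ci_high": float(np.quantile(arr, 1.0 - alpha)),
        }
    out["n_boot"] = n_boot
    out["ci"] = ci
    return out


def simulate_diffusion_trials(v: float, a: float, t0: float, n: int,
                              seed: int, dt: float = 1e-4,
                              max_t: float = 10.0) -> TrialSet:
    """Synthetic two-boundary diffusion data at known parameters.

    Unbiased start z = a/2, boundaries {0, a}, diffusion coefficient 1,
    Euler steps of ``dt`` seconds.  Used as the parameter-recovery ground
    truth for :func:`estimate_ddm`; RTs are reported in ms.
    """
    from .decision import TrialOutcome
    rng = np.random.default_rng(seed)
    x = np.full(n, a / 2.0)
    alive = np.ones(n, bool)
    rt = np.full(n, np.nan)
    upper = np.zeros(n, bool)
    sqdt = np.sqrt(dt)
    t = 0.0
    while alive.any() and t < max_t:
        t += dt
        idx = np.flatnonzero(alive)
        x[idx] += v * dt + sqdt * rng.standard_normal(len(idx))
        up = x[idx] >= a
        dn = x[idx] <= 0.0
        done = up | dn
        hit = idx[done]
        rt[hit] = t
        upper[hit] = up[done]
        alive[hit] = False
    outcomes = []
    for k in range(n):
        if np.isnan(rt[k]):
            outcomes.append(TrialOutcome("timeout", None, False, "timeout"))
        else:
            outcomes.append(TrialOutcome(
                "upper" if upper[k] else "lower",
                (rt[k] + t0) * 1000.0, True,
                "correct" if upper[k] else "error",
            ))
    return TrialSet(outcomes=tuple(outcomes), n=n, base_seed=seed)
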