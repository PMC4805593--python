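"""Two-population mutual-inhibition attractor dynamics of one action channel.

A single action channel is modelled as two competing rate populations: a
direct-pathway ("Go") population D that facilitates the action and an
indirect-pathway ("NoGo") population I that suppresses it.  Each population
excites itself and inhibits the other; selective cortical drive reaches them
through pathway-specific gains, while modulatory (cue-driven) and tonic
background drives reach both populations non-selectively.

The dynamics are leaky rate equations integrated by Euler-Maruyama:

    tau * dD/dt = -D + f(w_self*D - w_inh*I + g_d*I_d + I_m + I_lambda) + noise
    tau * dI/dt = -I + f(w_self*I - w_inh*D + g_i*I_i + I_m + I_lambda) + noise

with additive Gaussian noise of standard deviation ``noise_sd * sqrt(dt)``
per step and rectification of the state to non-negative rates.  ``f`` is a
threshold-linear (default) or logistic transfer function.  With sufficient
self-excitation (``w_self + w_inh > 1``) the channel is bistable: a
D-dominant "Go" attractor and an I-dominant "NoGo" attractor coexist with a
symmetric saddle between them, and small noise selects between them.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
from scipy import optimize

__all__ = [
    "Activation",
    "ChannelParams",
    "ChannelInput",
    "StateTrajectory",
    "FixedPoint",
    "FixedPointSet",
    "InstabilityError",
    "InvalidStateError",
    "step",
    "simulate_channel",
    "simulate_channel_batch",
    "gate_time",
    "find_fixed_points",
]

# Activity ceiling (rate units) above which integration is declared divergent.
ACTIVITY_CEILING = 10.0
# Merge tolerance for distinct fixed points (rate units).
FIXED_POINT_MERGE_TOL = 1e-6
# Dwell window (ms) a rate separation must persist to count as the gate.
GATE_DWELL_MS = 50.0


class InstabilityError(RuntimeError):
    """Raised when channel activity exceeds the configured ceiling."""

    def __init__(self, time_ms: float, value: float,
                 batch_index: Optional[int] = None, context: str = ""):
        self.time_ms = time_ms
        self.value = value
        self.batch_index = batch_index
        self.context = context
        msg = (f"channel activity {value:.3g} exceeded ceiling "
               f"{ACTIVITY_CEILING} at t = {time_ms:.6g} ms")
        if batch_index is not None:
            msg += f" (trial index {batch_index})"
        if context:
            msg += f" [{context}]"
        super().__init__(msg)


class InvalidStateError(ValueError):
    """Raised when a state or input is non-finite."""


@dataclass(frozen=True)
class Activation:
    """Transfer function of a rate population.

    kind
        ``"threshold-linear"``: f(u) = slope * max(u - offset, 0).
        ``"logistic"``: f(u) = fmax / (1 + exp(-slope * (u - offset))).
    """

    kind: Literal["threshold-linear", "logistic"] = "threshold-linear"
    slope: float = 1.0
    offset: float = 0.0
    fmax: float = ACTIVITY_CEILING

    def __post_init__(self):
        if self.kind not in ("threshold-linear", "logistic"):
            raise ValueError(f"unknown activation kind: {self.kind!r}")
        if self.slope <= 0:
            raise ValueError("activation slope must be > 0")
        if self.fmax <= 0:
            raise ValueError("activation fmax must be > 0")

    def __call__(self, u):
        if self.kind == "threshold-linear":
            return self.slope * np.maximum(np.asarray(u) - self.offset, 0.0)
        z = -self.slope * (np.asarray(u) - self.offset)
        return self.fmax / (1.0 + np.exp(z))


@dataclass(frozen=True)
class ChannelParams:
    """Dynamical constants of one action channel.

    tau
        Membrane/population time constant, ms.
    w_self, w_inh
        Recurrent self-excitation and cross-inhibition weights
        (dimensionless, >= 0).  Bistability requires w_self + w_inh > 1 in
        the threshold-linear regime.
    g_d, g_i
        Input sensitivities of the direct and indirect populations
        (dimensionless, > 0).  These are the cortico-striatal weights that
        phasic-dopamine learning modifies.
    activation
        Transfer function applied to the summed drive.
    noise_sd
        Within-step noise standard deviation (rate units); scaled by
        sqrt(dt) in the Euler-Maruyama update.
    dt
        Integration step, ms; must satisfy dt <= tau / 10.
    """

    tau: float = 100.0
    w_self: float = 0.8
    w_inh: float = 0.5
    g_d: float = 1.0
    g_i: float = 1.0
    activation: Activation = field(default_factory=Activation)
    noise_sd: float = 0.04
    dt: float = 1.0

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.dt > self.tau / 10.0:
            raise ValueError(
                f"dt = {self.dt} violates dt <= tau/10 (tau = {self.tau})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.w_self < 0 or self.w_inh < 0:
            raise ValueError("weights must be >= 0")
        if self.g_d <= 0 or self.g_i <= 0:
            raise ValueError("input sensitivities g_d, g_i must be > 0")

    def swapped(self) -> "ChannelParams":
        """Parameters with the direct/indirect roles exchanged."""
        return replace(self, g_d=self.g_i, g_i=self.g_d)


@dataclass(frozen=True)
class ChannelInput:
    """Drive terms of one action channel.

    I_d, I_i
        Selective drive to the direct / indirect population.
    I_m
        Modulatory non-selective drive (cue-driven baseline shift) reaching
        both populations.
    I_lambda
        Tonic non-specific background drive (the tonic-dopamine proxy)
        reaching both populations.

    By default the non-selective terms enter unweighted (they bypass the
    pathway gains g_d / g_i); set ``gain_nonselective=True`` to route them
    through the gains instead.
    """

    I_d: float = 0.0
    I_i: float = 0.0
    I_m: float = 0.0
    I_lambda: float = 0.0
    gain_nonselective: bool = False

    def __post_init__(self):
        vals = (self.I_d, self.I_i, self.I_m, self.I_lambda)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidStateError("channel inputs must be finite")
        if any(v < 0 for v in vals):
            raise ValueError("channel inputs must be >= 0")

    def swapped(self) -> "ChannelInput":
        return replace(self, I_d=self.I_i, I_i=self.I_d)


def params_fingerprint(params: ChannelParams, inp: ChannelInput) -> str:
    """Stable hash of a (params, input) pair, for trajectory provenance."""
    payload = json.dumps(
        {
            "tau": params.tau, "w_self": params.w_self, "w_inh": params.w_inh,
            "g_d": params.g_d, "g_i": params.g_i,
            "activation": [params.activation.kind, params.activation.slope,
                           params.activation.offset, params.activation.fmax],
            "noise_sd": params.noise_sd, "dt": params.dt,
            "I_d": inp.I_d, "I_i": inp.I_i, "I_m": inp.I_m,
            "I_lambda": inp.I_lambda,
            "gain_nonselective": inp.gain_nonselective,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class StateTrajectory:
    """Time-stamped firing rates of the direct (D) and indirect (I) populations."""

    times: np.ndarray
    d_rate: np.ndarray
    i_rate: np.ndarray
    seed: Optional[int] = None
    params_fingerprint: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, float)
        d = np.asarray(self.d_rate, float)
        i = np.asarray(self.i_rate, float)
        if not (len(t) == len(d) == len(i)):
            raise ValueError("times/d_rate/i_rate must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(d < 0) or np.any(i < 0):
            raise ValueError("rates must be non-negative (rectified dynamics)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "d_rate", d)
        object.__setattr__(self, "i_rate", i)

    def __len__(self) -> int:
        return len(self.times)


def _drive(d, i, params: ChannelParams, inp: ChannelInput):
    """Summed input to each population before the transfer function."""
    if inp.gain_nonselective:
        ns_d = params.g_d * (inp.I_m + inp.I_lambda)
        ns_i = params.g_i * (inp.I_m + inp.I_lambda)
    else:
        ns_d = ns_i = inp.I_m + inp.I_lambda
    u_d = params.w_self * d - params.w_inh * i + params.g_d * inp.I_d + ns_d
    u_i = params.w_self * i - params.w_inh * d + params.g_i * inp.I_i + ns_i
    return u_d, u_i


def step(d, i, params: ChannelParams, inp: ChannelInput, noise_pair=(0.0, 0.0)):
    """One Euler-Maruyama update of the channel state.

    ``noise_pair`` holds two standard-normal draws; they are scaled by
    ``noise_sd * sqrt(dt)`` here.  The returned state is rectified to >= 0.
    """
    d = np.asarray(d, float)
    i = np.asarray(i, float)
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(i))):
        raise InvalidStateError("non-finite channel state")
    u_d, u_i = _drive(d, i, params, inp)
    f = params.activation
    scale = params.noise_sd * math.sqrt(params.dt)
    d_next = d + (params.dt / params.tau) * (-d + f(u_d)) + scale * noise_pair[0]
    i_next = i + (params.dt / params.tau) * (-i + f(u_i)) + scale * noise_pair[1]
    return np.maximum(d_next, 0.0), np.maximum(i_next, 0.0)


def _n_steps(horizon: float, dt: float) -> int:
    # ceil with guard against float fuzz when horizon is a multiple of dt
    return int(math.ceil(horizon / dt - 1e-9))


def simulate_channel_batch(
    params: ChannelParams,
    inp: ChannelInput,
    horizon: float,
    seeds,
    d0: float = 0.0,
    i0: float = 0.0,
):
    """Integrate many independent channel realizations at once.

    Each element of ``seeds`` gets its own RNG stream, so a batch run is
    bit-identical to running :func:`simulate_channel` once per seed.
    Returns ``(times, d, i)`` with ``d``/``i`` of shape (n_seeds, n_samples).
    """
    if horizon < params.dt:
        raise ValueError("horizon must be >= dt")
    n_steps = _n_steps(horizon, params.dt)
    seeds = list(seeds)
    n = len(seeds)
    if params.noise_sd > 0:
        noise = np.empty((n, n_steps, 2))
        for k, s in enumerate(seeds):
            noise[k] = np.random.default_rng(s).standard_normal((n_steps, 2))
    else:
        noise = np.zeros((1, n_steps, 2))
        noise = np.broadcast_to(noise, (n, n_steps, 2))

    d = np.full(n, float(d0))
    i = np.full(n, float(i0))
    times = np.arange(n_steps + 1) * params.dt
    d_out = np.empty((n, n_steps + 1))
    i_out = np.empty((n, n_steps + 1))
    d_out[:, 0] = d
    i_out[:, 0] = i
    for k in range(n_steps):
        d, i = step(d, i, params, inp, (noise[:, k, 0], noise[:, k, 1]))
        hi = max(d.max(initial=0.0), i.max(initial=0.0))
        if hi > ACTIVITY_CEILING:
            peak = np.maximum(d, i)
            raise InstabilityError(times[k + 1], hi,
                                   batch_index=int(np.argmax(peak)))
        d_out[:, k + 1] = d
        i_out[:, k + 1] = i
    return times, d_out, i_out


def simulate_channel(
    params: ChannelParams,
    inp: ChannelInput,
    horizon: float,
    seed: int = 0,
    d0: float = 0.0,
    i0: float = 0.0,
) -> StateTrajectory:
    """Simulate one channel for ``horizon`` ms from state (d0, i0).

    The trajectory has ceil(horizon/dt)+1 samples including t = 0 and is
    bit-reproducible for a given seed.  Raises :class:`InstabilityError`,
    naming the first offending time, if activity exceeds the ceiling.
    """
    times, d, i = simulate_channel_batch(params, inp, horizon, [seed], d0, i0)
    return StateTrajectory(
        times=times, d_rate=d[0], i_rate=i[0], seed=seed,
        params_fingerprint=params_fingerprint(params, inp),
    )


def gate_time(
    traj: StateTrajectory,
    separation: float,
    dwell_ms: float = GATE_DWELL_MS,
) -> Optional[float]:
    """First time the |D - I| separation reaches and holds the criterion.

    The gate marks the nonlinear divergence of the two pathways — the
    transition from deliberation toward commitment.  The separation must
    persist for ``dwell_ms`` (or to the end of the trajectory if less
    remains) to discount transient noise-driven crossings.  Returns None if
    the criterion is never met.
    """
    if separation <= 0:
        raise ValueError("separation must be > 0")
    diff = np.abs(traj.d_rate - traj.i_rate)
    ok = diff >= separation
    if not ok.any():
        return None
    dt = traj.times[1] - traj.times[0] if len(traj) > 1 else 1.0
    dwell_n = max(int(round(dwell_ms / dt)), 1)
    n = len(ok)
    for idx in np.flatnonzero(ok):
        end = min(idx + dwell_n, n)
        if ok[idx:end].all():
            return float(traj.times[idx])
    return None


@dataclass(frozen=True)
class FixedPoint:
    d: float
    i: float
    stability: Literal["stable", "saddle", "unstable"]
    eigenvalues: tuple


@dataclass(frozen=True)
class FixedPointSet:
    points: tuple
    n_unconverged: int = 0

    @property
    def stable(self):
        return [p for p in self.points if p.stability == "stable"]

    @property
    def saddles(self):
        return [p for p in self.points if p.stability == "saddle"]


def _rhs(x, params: ChannelParams, inp: ChannelInput):
    d, i = x
    u_d, u_i = _drive(d, i, params, inp)
    f = params.activation
    return np.array([(-d + float(f(u_d))) / params.tau,
                     (-i + float(f(u_i))) / params.tau])


def find_fixed_points(
    params: ChannelParams,
    inp: ChannelInput,
    grid_n: int = 13,
    merge_tol: float = FIXED_POINT_MERGE_TOL,
) -> FixedPointSet:
    """Locate equilibria of the zero-noise dynamics and classify stability.

    Candidates are seeded on a ``grid_n`` x ``grid_n`` grid over
    [0, ceiling]^2, polished with a Newton-type root finder, merged at
    ``merge_tol``, and classified from the eigenvalues of the numerical
    2x2 Jacobian (central differences).  Candidates whose polishing fails
    are counted in ``n_unconverged`` rather than raising.
    """
    grid = np.linspace(0.0, ACTIVITY_CEILING, grid_n)
    found: list[np.ndarray] = []
    n_fail = 0
    for d0 in grid:
        for i0 in grid:
            sol = optimize.root(_rhs, [d0, i0], args=(params, inp), method="hybr")
            if not sol.success:
                n_fail += 1
                continue
            x = sol.x
            # Discard spurious negative-rate roots; snap rectified zeros.
            if x.min() < -1e-8 or x.max() > ACTIVITY_CEILING + 1e-8:
                continue
            x = np.maximum(x, 0.0)
            if np.abs(_rhs(x, params, inp)).max() > 1e-9:
                continue
            if not any(np.abs(x - y).max() <= merge_tol for y in found):
                found.append(x)

    pts = []
    eps = 1e-6
    for x in found:
        jac = np.empty((2, 2))
        for col in range(2):
            hp = x.copy()
            hm = x.copy()
            hp[col] += eps
            hm[col] = max(hm[col] - eps, 0.0)  # one-sided at the rectification wall
            h = hp[col] - hm[col]
            jac[:, col] = (_rhs(hp, params, inp) - _rhs(hm, params, inp)) / h
        ev = np.linalg.eigvals(jac)
        re = np.real(ev)
        if np.all(re < 0):
            label = "stable"
        elif np.any(re < 0) and np.any(re > 0):
            label = "saddle"
        else:
            label = "unstable"
        pts.append(FixedPoint(float(x[0]), float(x[1]), label,
                              tuple(complex(e) for e in ev)))
    pts.sort(key=lambda p: (p.d, p.i))
    return FixedPointSet(points=tuple(pts), n_unconverged=n_fail)
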