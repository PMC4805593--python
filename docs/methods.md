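# Methods

`bgcompete` simulates action selection as a competition between the two
striatal control pathways of one action channel and reads the competition
out as an accumulate-to-threshold decision. This note records the model,
its parameters and defaults, the numerical choices, and what the simulator
does and does not capture.

## Channel dynamics

Each action channel holds two rate populations: the direct-pathway
population `D` (facilitates the action) and the indirect-pathway population
`I` (suppresses it). They evolve by leaky rate equations with recurrent
self-excitation and mutual inhibition,

    tau dD/dt = -D + f(w_self D - w_inh I + g_d I_d + I_m + I_lambda) + xi_D
    tau dI/dt = -I + f(w_self I - w_inh D + g_i I_i + I_m + I_lambda) + xi_I

integrated by Euler–Maruyama at step `dt` with additive Gaussian noise of
standard deviation `noise_sd * sqrt(dt)` per step, and rectification of the
state to non-negative rates. `I_d`, `I_i` are selective cortical drives
scaled by the pathway sensitivities `g_d`, `g_i`; `I_m` (cue-driven) and
`I_lambda` (tonic background) are non-selective and by default enter
unweighted; setting `gain_nonselective=True` routes them through the
pathway gains instead (used by the tonic-sweep preset, where the background
input shares the cortico-striatal weights).

`f` is threshold-linear by default, `f(u) = slope * max(u - offset, 0)`; a
logistic option is provided. Activities are dimensionless "rate units" in
[0, 10]; exceeding the ceiling raises an instability error naming the first
offending time. Units match the unlabeled firing-rate axes this class of
model is usually plotted with; all times are ms.

With `w_self + w_inh > 1` the zero-noise channel is bistable under
symmetric drive: a D-dominant ("Go") and an I-dominant ("NoGo") attractor
coexist with a symmetric saddle, and per-step noise selects between them.
The default constants `tau = 100 ms`, `w_self = 0.8`, `w_inh = 0.5`,
`dt = 1 ms` put the channel in this regime; closed-form checks (winner at
`c/(1 - w_self)`, saddle at `c/(1 - w_self + w_inh)` for symmetric drive
`c`) are tested against the grid-seeded root finder and a dense-grid
forward-integration oracle.

`gate_time` reports the first moment `|D - I|` reaches a separation
criterion and holds it for a 50 ms dwell window (robustness against
transient noise crossings). `find_fixed_points` polishes a 13x13 grid of
candidates with a Newton-type root finder, merges duplicates at 1e-6 rate
units, and classifies stability from the numerical Jacobian (one-sided
differences at the rectification wall).

## Decision readout

The decision variable integrates the *normalized* pathway difference,

    evidence(t) = sum_k beta (D_k - I_k) / (D_k + I_k + eps) dt,

with gain `beta` (default 0.005 /ms) and guard `eps = 1e-3`. The normalized
form is bounded in [-1, 1] and degenerates gracefully at rest. A "go" is
emitted at the first crossing of the execution threshold `theta` before the
deadline (closed right endpoint: a crossing exactly at the deadline sample
counts); otherwise the trial is a no-go. There is no lower absorbing bound
— transient Skeptic dominance makes evidence negative but never triggers an
outcome by itself. Non-decision time `t0` is added to crossing times.

Defaults for the single-channel go/no-go task: `theta = 2.5`,
`deadline = 1200 ms`, `noise_sd = 0.04`. At these values the documented
input-ratio grid (I_d:I_i in {1.2, 1.7, 2.4, 3.3, 4.5} at unit total drive)
spans go-rates of roughly 0.5 to 0.98 with mean go RT falling from ~850 to
~720 ms, so both commitment and speed are strictly ordered by the ratio at
500 trials per point.

## Cued two-channel choice

Two channels (left/right) race; the first evidence trace to reach threshold
wins, a same-sample tie is broken uniformly at random from the trial's RNG
stream, and a double miss is a timeout. Sensory input enters the channel
matching the stimulus as constant drive `sensory_gain * (base + coherence)`
split `direct_bias : (1 - direct_bias)` between the direct and indirect
populations (default bias 0.6, reflecting the denser sensory innervation of
direct-pathway neurons); the other channel receives the unmodulated base
drive. The cue delivers non-selective drive `I_m = cue_strength` to both
populations of the cued channel from trial onset.

An important operating-point choice: under the normalized-difference
readout, the *linear* regime of the channel is invariant to the overall
drive scale — both coherence and a baseline shift would change only the
noise-to-signal ratio, and a non-selective baseline shift would, if
anything, slow the readout by inflating the denominator. The cued channels
therefore run above a threshold-linear activation offset (0.2), where a
baseline shift moves the populations into the responsive region sooner and
genuinely accelerates the separation. This is the mechanism by which a
valid cue speeds correct responses and an invalid cue drives fast errors;
with `cue_strength = 0` the valid/invalid cells are statistically
identical. Defaults: coherence 0.3, cue_strength 0.15, `theta = 2.0`,
deadline 1500 ms.

## Reinforcement layer

A probabilistic-selection session presents one stimulus pair with reward
probabilities `p_opt >= p_sub` (presets 0.80/0.20, 0.70/0.30, 0.60/0.40 —
the conventional large/medium/small gaps of this task family). Choices come
from a race between two constant-drift accumulators

    X_a(t) = v_a t + sigma W(t),   v_opt/sub = drift_base +/- slope (Q_opt - Q_sub)/2

(defaults: drift_base 0.0025 /ms, slope 0.003 /ms per unit Q-difference,
sigma 0.05 /sqrt(ms), race step 5 ms, threshold and deadline shared with
the decision readout). Exploration is not a policy parameter: accumulator
noise alone samples the lower-valued action, and sampling pressure fades as
the value gap grows. A double timeout falls back to an unbiased forced
guess that is still rewarded and learned from.

After feedback the chosen action's value follows the delta rule on the
reward-prediction error, `Q <- Q + alpha (r - Q)` (default alpha 0.05), and
its pathway sensitivities receive the phasic-dopamine update: `+delta` to
the direct and `-delta` to the indirect sensitivity after reward, reversed
after non-reward, clamped to [0.2, 3.0] (default delta 0.01; an
RPE-magnitude-scaled variant is available as `rpe_scaled_delta`). The gain
layer lets the full network generate choices from learned sensitivities
(`network_race_trial`); the abstract Q/drift race is the fast default.

Two practical notes. First, the delta rule converges to the true reward
probabilities only under persistent sampling of both arms; the default
drift mapping keeps late-session choice of the suboptimal arm frequent
enough (~15–25%) that terminal `Q_opt - Q_sub` sits within ±0.05 of
`p_opt - p_sub` over 100 sessions of 1000 trials. Second, terminal value
differences carry a small positive bias (~+0.02 at the 70/30 schedule)
because the suboptimal arm is resampled preferentially when its estimate
drifts high — a known consequence of choice-contingent sampling, visible in
any on-policy learner of this type.

## Tonic background drive

Tonic dopamine is modelled as the level of `I_lambda`. The sweep preset
uses a channel with stronger cortical weighting of the direct pathway
(`g_d = 1.2 > g_i = 0.8`, equal selective drive, `w_self = 0.7`,
activation offset 0.6, `noise_sd = 0.06`, `theta = 2.0`, deadline 2500 ms)
and routes the background drive through those gains. At low `I_lambda`
(0.2) the operating point is subthreshold: commitment waits on noise-driven
escape, so responses are slow, variable, and often withheld — exploratory
behaviour. At high `I_lambda` (1.2) the network is driven past its offset
from the start: gating is early, decisions fast and tight — exploitation.
Across the preset levels (0.2, 0.7, 1.2) mean RT, RT variability, and gate
time all fall strictly while go-rate rises, at 1000 trials per level.

For the value-based race the same lever enters as a multiplicative
excitability gain, scaling both accumulators' drifts by
`1 + tonic_drift_gain * I_lambda` (default gain 2.0). The multiplicative
form matters: it shortens decision times while *improving* discrimination
(drift separation grows with the gain faster than integrated noise), so
choice entropy at a fixed value difference falls with tonic drive. A purely
additive base shift would do the opposite — quicker but less discriminating
choices. Sweeps only ever read learning state; they never modify gains or
values.

## Effective diffusion parameters

`estimate_ddm` inverts accuracy, correct-RT mean and correct-RT variance
into drift `v`, boundary separation `a` and non-decision time `t0` of the
two-boundary constant-drift diffusion via the closed-form moment equations
(EZ-diffusion, diffusion coefficient s = 1). Accuracies of exactly 0, 0.5
or 1 are edge-corrected by 1/(2n) so the inversion stays defined and
continuous. RTs convert ms -> s only at this module's boundary, and the
correct-RT vector is sorted before the moments so the estimate is exactly
invariant to trial order. On synthetic diffusion data (Euler at 0.1 ms,
n = 5000) all three parameters recover within a few percent; across cued
conditions differing only in the direct-routing bias the estimated drift is
strictly increasing while the boundary stays within its recovery error —
the signature that pathway-ratio manipulations act on drift, not threshold.
`compare_conditions` gives trial-level bootstrap percentile intervals on
parameter differences. Out of scope: likelihood or hierarchical fitting and
between-trial variability parameters.

## Reproducibility and I/O

One master seed; every stream (trials, channels, schedules, rewards,
bootstraps) uses a SHA-256-derived child seed keyed by a label and index,
so batch simulation is bit-identical to trial-by-trial simulation and any
CLI invocation repeated with the same config and seed writes byte-identical
CSV/JSON. Derived seeds live in [0, 2^31); at that size a hundred thousand
streams incur a handful of birthday collisions in expectation, which is
harmless here since colliding streams still differ in their role. CSVs are
comma-separated UTF-8 with a header, '.' decimal, empty field = missing
(absent RTs are never written as 0); every artifact gets a JSON sidecar
with the config fingerprint, master seed and package version.

## What the simulator does and does not show

All inputs are configuration — the simulator is its own data generator, and
the tests certify internal, mechanistic properties: symmetry nulls, exact
monotonicities, attractor structure, convergence of the learning rule,
ordering of learning speed by reward gap, and the exploration/exploitation
gradient under tonic drive. Passing them shows the implementation realizes
the intended circuit logic at the documented operating points. It does not
show that real basal-ganglia recordings or human behaviour quantitatively
match: there are no fits to empirical RT distributions, no spiking or
conductance dynamics, no explicit pallidal/thalamic/subthalamic nodes, no
hyper-direct (reactive stopping) pathway, and no collapsing bounds or
between-trial variability in the diffusion abstraction. Parameter defaults
were chosen once as documented, physiologically sensible operating points
of this reduced model, not estimated from data.
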