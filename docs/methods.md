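# Methods

This note documents the model, the numerical choices, and what the synthetic
subject does and does not emulate. Parameter names refer to the public API.

## State estimation

The stress state is operationalized as the weighted sum of standardized
responses across physiological channels. Standardization is Hedges' g against
a resting baseline measured shortly before the session (`baseline_measurement`,
default minimum 60 s, subject at rest — measuring with an active stressor is a
protocol error). The combination

s_c = Σ d_i g_i w_i / Σ w_i

is normalized by the weight sum so the state is a weighted *average* in
baseline-SD units, invariant under rescaling of the weight vector; weights are
non-negative with at least one positive, default all 1.

Two deliberate additions to the plain summation:

* **Direction signs** d_i ∈ {+1, −1} (default +1 — the literal summation).
  Channels such as heart rate variability decrease under sympathetic load;
  without a sign convention their g would *subtract* from the state. The
  default channel set ships HRV with d = −1.
* **During the loop**, g is computed against the session-start baseline (not a
  rolling window). A rolling baseline would let slow drift silently redefine
  "rest"; the drift is instead treated as a disturbance for the controller to
  cancel. Callers may supply any `BaselineStats` to use a different convention.

Analysis windows are half-open — pre = [t−pre, t), post = [t+settle, t+post) —
so the sample at the event timestamp belongs to the response side. Channels are
windowed independently and may run at different sampling rates; a window is
valid only if the log spans it and contributes ≥ 2 samples per side, otherwise
the trial is dropped (never imputed).

## Rules and their fitting

Discrete rules are matrices over the L·(L−1) ordered level transitions; columns
are arithmetic means of per-channel Δg over repeated trials of that transition
(repetition averages out uncontrolled variation; no weighting scheme is applied
because trials are exchangeable by design). Transitions never observed are
flagged unavailable and excluded from candidate search.

Continuous rules regress the measured Δg on the absolute adjustment value x by
ordinary least squares, one simple regression per channel (solved jointly via a
QR-based least-squares call; the test suite checks agreement with the
closed-form normal equations to 1e-9). Fitting requires ≥ 2 trials with ≥ 2
distinct x values; identical x values raise a rank-deficiency error.

Both rule kinds predict the scalar state change by the same normalized weighted
combination as the state itself. Normalizing the discrete prediction (rather
than leaving it a raw weighted sum) is required for the two rule kinds to
predict on a common scale and compete in one argmin; `strict_paper=True` on
`predict_discrete` restores the unnormalized form for comparison.

Standardization sigma during fitting: each trial's pre-window SD by default,
floored at `sigma_floor_frac` (default 1e-6) of the global session-baseline
sigma so that a near-constant pre-window cannot explode g; a zero global sigma
is always an error. `sigma_source="global"` uses the session sigma throughout —
preferable when trials are short relative to the noise bandwidth.

`post_settle_s` (default 0) skips the first seconds of the post window so the
mean measures the settled response rather than the rise. The examples and the
acceptance runs use 2.5 s ≈ latency + 4 decay time-constants of the profiles
they run against; without it the onset transient attenuates fitted slopes by
roughly (latency + tau)/post_window.

The protocol builder presents continuous trials *transiently* (duration = post
window) even for characteristics that are controlled state-wise later: a
persistent setting would leak into the next trial's pre-window and turn the
regression on absolute x into a regression on differences of consecutive x.
Discrete transitions are presented state-wise along an Eulerian circuit of the
transition graph (a transition can only be taken from the level the subject is
at); every ordered transition occurs exactly once per circuit, `repetitions`
circuits per protocol, interleaved at random with the continuous trials.

## The controller

Candidates: per discrete rule, the available transitions leaving the current
level; per continuous rule, the single x from inverting the aggregated affine
prediction toward the target, clamped to the domain and snapped to the nearest
catalog stimulus where applicable. Ties in stimulus lookup break toward the
lower derived scale, then lexicographic id. A rule whose aggregate slope is
below `epsilon` (default 1e-8) is non-invertible: it contributes the domain
endpoint whose prediction lies closest to the target, or nothing at all if it
predicts no change anywhere (so a fully null model idles rather than actuating
at random).

Selection minimizes the absolute distance |s_d − (s_c + Δŝ)| (the "closest to
the desired state" reading). The tie-break compares, on the channel k =
argmax_i |s_d − g_i|, the magnitude of each candidate's predicted per-channel
change, preferring the larger — the floor/ceiling-avoidance heuristic. "Value"
here is the channel's g, not its raw signal level: g is the only quantity
commensurate with the scalar target. Residual ties resolve by characteristic
name, then payload, making selection a total order (verified against a
brute-force oracle).

**Offset-aware inversion.** For a state-wise continuous characteristic the rule
predicts the response to a value x relative to neutral, while the subject is
already experiencing the response to the currently applied x_cur. The candidate
therefore inverts (s_d − s_c) + Δŝ(x_cur) and reports Δŝ(x_new) − Δŝ(x_cur) as
its predicted change. With the plain inversion of (s_d − s_c) a persistent
actuator alternates between target and rest (choose x to add the full gap, the
gap closes, choose x ≈ neutral, the state collapses, repeat);the corrected
form is deadbeat and reduces to the plain form whenever the characteristic is
inactive. `account_current=False` restores the literal behavior.

Loop timing: default period 5 s (responses latencies live in the realm of
seconds), state estimated from the trailing `state_window_s` = 2.5 s so the
window reads the settled response to the previous action rather than its rise;
the period must cover the state window. An optional refractory interval can
further delay re-evaluation. The desired state may be a constant or a
piecewise-constant trajectory. If all candidates move the state away from the
target the controller still applies the least-bad argmin, logged as such; on
window dropout the iteration is logged as a gap and the last valid state
carries over.

## Synthetic subject

Per channel: sample = clip(mu + drift + Σ effects + noise, floor, ceiling) on a
fixed grid ((k+1)/rate), with white noise, an AR(1) wander parameterized by
stationary SD and time constant (per-sample coefficients derived from each
channel's rate, so the process is rate-independent), and additive adjustment
effects with envelope 1 − exp(−(t − onset − latency)/tau); transient or
replaced effects decay with the same tau from the level reached. Concurrent
effects add before clipping. Noise and drift draw from separate per-channel
substreams of one seed, so a trace is reproducible for a fixed (seed, schedule)
regardless of how the timeline is chunked.

Ground-truth continuous responses are affine in x, matching the rule family so
parameter recovery is well-posed; the `quadratic` profile adds curvature to
probe the linear model's misspecification. Discrete ground truth is stored as
per-level offsets, so transition effects telescope and within-subject response
consistency holds by construction.

Profile defaults (nominal resting values: HR 70±5 bpm, RMSSD 45±8 ms, SBP
120±6 mmHg, SCL 2.0±0.4 µS; full-intensity responses +5 bpm, −8 ms, +4.5 mmHg,
+0.5 µS): `easy` = noise SD 0.1× nominal sigma, no drift, latency 0.5 s, tau
0.5 s; `noisy` = 0.5× noise, mild drift, latency 1 s, tau 2 s; `drifting` =
easy noise plus wander with stationary SD 0.3× sigma and 120 s time constant;
`saturating` = bounds at ±0.5× the largest response so clipping is reachable.
These magnitudes are simulator choices on the order of commonly reported acute
stress responses, not empirical claims.

What the simulator does *not* emulate: waveform morphology (ECG complexes,
pulse waves — channels are derived-value streams as acquisition software
emits), habituation/sensitization, interactions between concurrent stressors
(effects are additive), context-dependent or time-varying response rules.
Passing tests therefore demonstrate the estimator/fitter/controller machinery
under the stated response model, not validity on human data.

## Problem sizes and determinism

The test and acceptance runs use desk-scale sessions: fitting protocols of
24–80 trials at 25 s spacing, 10-minute control sessions at a 5 s period,
and replicate counts of 100 (slope recovery) and 20 (paired tracking). All
randomness flows from explicit seeds through `numpy.random.default_rng`;
repeated runs produce byte-identical models, session frames and reports
(timestamps are seconds from session start, never wall-clock). Serialized
models store floats at full precision via JSON shortest round-trip formatting,
so matrices survive write/read bit-exactly.

## Known limitations

* Rules are linear and static; no online refitting, interaction terms, or
  uncertainty intervals on coefficients.
* One adjustment per period with one-step lookahead; no model-predictive
  planning across periods.
* The tie-break interprets "farthest channel" on the g scale; other readings
  (raw signal distance to a physiological bound) are plausible but not
  implemented.
* The artifact is simulator-facing: no acquisition drivers, no safety
  interlocks for live human use.
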