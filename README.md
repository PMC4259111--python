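# stressloop

Closed-loop control of a physiological stress state — a *biocybernetic loop* at
desk scale, for psychophysiology and physiological-computing researchers who
want to estimate a scalar stress state from multi-channel signals, calibrate
per-subject stressor-response rules, and drive the state toward a target by
automatically adjusting the stressor. A synthetic-subject simulator stands in
for the human, the stimulus environment and the acquisition hardware, so the
whole loop runs (and is tested) from plain text files and seeds.

## The model

**State estimation.** Each channel *i* (heart rate, heart rate variability,
blood pressure, electrodermal activity, …) is standardized against a resting
baseline as a standardized mean difference (Hedges' g):

    g_i = (mu_response,i − mu_baseline,i) / sigma_baseline,i

The scalar physiological activity state — used directly as the current stress
state s_c — is the weighted average of direction-adjusted channel responses:

    s_c = p_c = Σ_i d_i · g_i · w_i / Σ_i w_i ,   w_i ≥ 0 (default 1), d_i ∈ {+1, −1}

so s_c is expressed in weighted-average baseline SDs and starts near 0 at rest.
Direction signs let channels that conventionally *decrease* under stress (HRV)
contribute with the right sign.

**Rules.** For every adjustable stressor characteristic the feedback model
holds exactly one rule predicting the per-channel response change Δg:

* *discrete* (level-based, e.g. first-/third-person realism): a matrix **D**
  with one row per channel and one column per ordered level transition
  (L·(L−1) columns — e.g. a 4×2 matrix for 2 levels over 4 channels), fitted as
  per-transition means over repeated trials;
* *continuous* (scale-based, e.g. rated aversive images, soundscape intensity):
  per-channel simple linear regressions Δĝ_i = β0_i + β1_i·x, fitted by
  ordinary least squares, invertible in closed form for the x predicted to
  produce a desired state change.

Both rule kinds predict a scalar state change Δŝ by the same weighted average
as p_c, so they compete on one scale.

**Control.** Every loop period (default 5 s) the controller estimates s_c from
the most recent samples, enumerates all applicable adjustments (transitions
leaving the current level; the inverted continuous value, snapped to the
nearest catalog stimulus when catalog-backed) and applies the argmin of
|s_d − (s_c + Δŝ)|. Ties go to the candidate with the largest predicted effect
on the channel whose g lies farthest from the target — steering load away from
channels near their physiological floor/ceiling — then to name/payload order.
Exactly one adjustment (or an explicit no-action) per iteration; drift and
spontaneous changes are corrected on the next pass.

**Synthetic subject.** Per channel: baseline mean/SD, white noise, slow AR(1)
wander, response latency and exponential rise/decay time constants, saturation
bounds, and ground-truth responses per characteristic (affine in x, or
per-transition shifts). Named profiles: `easy`, `noisy`, `drifting`,
`saturating`, `quadratic` (deliberately misspecified).

## Worked example

`python examples/04_closed_loop.py` fits a model on a drifting simulated
subject, then runs a 10-minute controlled session against the matched
uncontrolled run (identical noise and drift realization):

```
iterations: 120, adjustments applied: 120
mean |s_d - s_c|: 0.271 (final third 0.234)
time within +/-0.5 band: 88.3%
uncontrolled final-third error: 1.367
controlled/uncontrolled error ratio: 0.17
```

The target was s_d = 2.0 baseline SDs. Uncontrolled, the subject idles around
its baseline and drifts, leaving a mean error ≈ 1.4; with the loop closed the
controller holds the state at the target within ≈ 0.23 SD — an 83% reduction.
`examples/01–03` walk the individual stages (state estimation, stimulus-scale
derivation, rule fitting with ground-truth recovery).

A thin CLI mirrors the library for shell pipelines
(`stressloop simulate|fit|control|evaluate`, see `stressloop --help`);
all artifacts are schema-versioned delimited/structured text.

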