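"""Synthetic physiological subject.

Stands in for the human + stimulus environment + acquisition chain so the whole
feedback loop can run at desk scale. Each channel emits a derived-value stream
(as acquisition software would, e.g. beat-averaged heart rate) at its own
sampling rate:

    sample(t) = clip(mu + drift(t) + sum_k shift_k * env_k(t) + noise, floor, ceiling)

* ``mu`` is the resting mean; ``noise`` is white with SD ``noise_sd``.
* ``drift`` is a slow first-order autoregressive wander with stationary SD
  ``drift_sd`` and time constant ``drift_tau_s`` (per-channel AR(1)
  coefficients are derived from the channel's sampling rate).
* Each applied adjustment contributes an effect with asymptotic per-channel
  ``shift`` (signal units) and envelope
  env(t) = 1 - exp(-(t - onset - latency)/tau) after a response latency;
  transient adjustments decay back toward baseline with the same time constant
  after their duration, state-wise ones persist until replaced/reverted.
* Concurrent effects add before clipping to the physiological bounds
  [floor, ceiling], realizing floor/ceiling saturation.

The design honors the requirements the loop places on response types:
responsivity (nonzero ground-truth shifts), within-subject response consistency
(identical adjustment -> identical deterministic effect), and seconds-scale
latency. Ground-truth continuous responses are affine in the adjustment value
x — matching the feedback model's assumption so parameter recovery is
well-posed; a deliberately misspecified quadratic profile exercises the linear
model's robustness. Identical (seed, schedule) reproduces the trace exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .characteristics import Adjustment, CharacteristicSpec, make_catalog
from .errors import ConfigError, ReportError, SimulationError, SpecError
from .rules import ContinuousRule, DiscreteRule, FeedbackModel
from .signal_model import BaselineStats, Channel, ChannelSet, SignalLog

PROFILES = ("easy", "noisy", "saturating", "drifting", "quadratic")


@dataclass
class SubjectModel:
    """Ground-truth parameters of a synthetic subject."""

    channels: ChannelSet
    baseline_mu: np.ndarray      # resting mean, signal units
    baseline_sigma: np.ndarray   # nominal resting SD, signal units (standardization scale)
    noise_sd: np.ndarray         # white sampling noise SD, signal units
    floor: np.ndarray
    ceiling: np.ndarray
    drift_tau_s: float = 120.0   # AR(1) time constant of the slow wander
    drift_sd: np.ndarray | None = None  # stationary SD of the wander (None/zeros = no drift)
    latency_s: float = 0.5
    decay_tau_s: float = 1.0
    # per characteristic, per channel asymptotic shifts in signal units:
    continuous_truth: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)  # (gamma0, gamma1)
    quadratic_truth: dict[str, np.ndarray] = field(default_factory=dict)  # gamma2 (0 = linear)
    level_offsets: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.channels)
        self.baseline_mu = np.asarray(self.baseline_mu, dtype=float)
        self.baseline_sigma = np.asarray(self.baseline_sigma, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        self.floor = np.asarray(self.floor, dtype=float)
        self.ceiling = np.asarray(self.ceiling, dtype=float)
        if self.drift_sd is None:
            self.drift_sd = np.zeros(n)
        self.drift_sd = np.asarray(self.drift_sd, dtype=float)
        for arr, label in ((self.baseline_mu, "baseline_mu"), (self.baseline_sigma, "baseline_sigma"),
                           (self.noise_sd, "noise_sd"), (self.floor, "floor"),
                           (self.ceiling, "ceiling"), (self.drift_sd, "drift_sd")):
            if arr.shape != (n,):
                raise SimulationError(f"{label} must have one entry per channel")
        if np.any(self.baseline_sigma <= 0) or np.any(self.noise_sd < 0) or np.any(self.drift_sd < 0):
            raise SimulationError("sigma must be > 0 and noise/drift SDs >= 0")
        if not (np.all(self.floor < self.baseline_mu) and np.all(self.baseline_mu < self.ceiling)):
            raise SimulationError("floor < baseline_mu < ceiling required")
        if self.latency_s < 0 or self.decay_tau_s <= 0 or self.drift_tau_s <= 0:
            raise SimulationError("latency_s >= 0 and time constants > 0 required")

    def transition_shift(self, characteristic: str, from_level: str, to_level: str) -> np.ndarray:
        """Asymptotic per-channel shift of a level transition (offset difference)."""
        offsets = self.level_offsets[characteristic]
        return offsets[to_level] - offsets[from_level]

    def continuous_shift(self, characteristic: str, x: float) -> np.ndarray:
        gamma0, gamma1 = self.continuous_truth[characteristic]
        shift = gamma0 + gamma1 * float(x)
        gamma2 = self.quadratic_truth.get(characteristic)
        if gamma2 is not None:
            shift = shift + gamma2 * float(x) ** 2
        return shift

    def nominal_baseline(self, duration_s: float = 60.0) -> BaselineStats:
        """Baseline stats from the model's nominal parameters (no measurement)."""
        n = np.maximum((duration_s * self.channels.sampling_rates).astype(int), 2)
        return BaselineStats(self.channels, self.baseline_mu.copy(), self.baseline_sigma.copy(),
                             n, duration_s)


@dataclass
class _Effect:
    shift: np.ndarray
    onset: float
    end: float | None = None  # offset time (transient end / replacement); None = persisting
    characteristic: str = ""

    def envelope(self, t: np.ndarray, latency: float, tau: float) -> np.ndarray:
        rise_start = self.onset + latency
        env = np.where(t > rise_start, -np.expm1(-np.maximum(t - rise_start, 0.0) / tau), 0.0)
        if self.end is not None:
            at_end = -math.expm1(-max(self.end - rise_start, 0.0) / tau)
            decayed = at_end * np.exp(-np.maximum(t - self.end, 0.0) / tau)
            env = np.where(t > self.end, decayed, env)
        return env

    def dead_after(self, t: float, latency: float, tau: float) -> bool:
        return self.end is not None and t - self.end > 30.0 * tau


class SubjectSimulator:
    """Stateful sample generator for one :class:`SubjectModel`.

    Samples lie on a fixed per-channel grid ((k+1)/rate from session start), so
    traces are reproducible regardless of how time is chunked. A single seed is
    split into stable per-channel sub-streams.
    """

    def __init__(self, model: SubjectModel, initial_levels: dict[str, str] | None = None, t0: float = 0.0):
        self.model = model
        self.t = float(t0)
        n = len(model.channels)
        # independent sub-streams per channel for noise vs. drift, so chunking
        # the timeline can never reorder draws between the two processes
        self._noise_rngs = [np.random.default_rng([int(model.seed), i, 0]) for i in range(n)]
        self._drift_rngs = [np.random.default_rng([int(model.seed), i, 1]) for i in range(n)]
        self._sample_count = np.zeros(n, dtype=np.int64)
        self._drift_state = np.zeros(n)
        self._effects: list[_Effect] = []
        self.current_levels: dict[str, str] = dict(initial_levels or {})
        for char, offsets in model.level_offsets.items():
            self.current_levels.setdefault(char, next(iter(offsets)))
        self._active_continuous: dict[str, tuple[_Effect, float]] = {}
        self.adjustments_applied = 0

    # -- actuation ---------------------------------------------------------

    def apply(self, adj: Adjustment, t: float | None = None) -> None:
        """Apply one stressor adjustment at time t (default: current time)."""
        t = self.t if t is None else float(t)
        if t < self.t - 1e-12:
            raise SimulationError("adjustments must be applied at non-decreasing times")
        end = t + adj.duration_s if adj.presentation == "transient" else None
        if adj.is_discrete:
            if adj.characteristic not in self.model.level_offsets:
                raise SimulationError(f"subject has no ground truth for {adj.characteristic!r}")
            if self.current_levels[adj.characteristic] != adj.from_level:
                raise SimulationError(
                    f"{adj.characteristic!r} is at {self.current_levels[adj.characteristic]!r}, "
                    f"not {adj.from_level!r}")
            shift = self.model.transition_shift(adj.characteristic, adj.from_level, adj.to_level)
            if adj.presentation == "state_wise":
                self.current_levels[adj.characteristic] = adj.to_level
        else:
            if adj.characteristic not in self.model.continuous_truth:
                raise SimulationError(f"subject has no ground truth for {adj.characteristic!r}")
            shift = self.model.continuous_shift(adj.characteristic, adj.value)
            if adj.presentation == "state_wise":
                prev = self._active_continuous.get(adj.characteristic)
                if prev is not None:
                    prev[0].end = t  # replaced: old effect decays from here
        effect = _Effect(shift=shift, onset=t, end=end, characteristic=adj.characteristic)
        if not adj.is_discrete and adj.presentation == "state_wise":
            self._active_continuous[adj.characteristic] = (effect, float(adj.value))
        self._effects.append(effect)
        self.adjustments_applied += 1

    def active_continuous_value(self, characteristic: str) -> float | None:
        """Currently applied state-wise value of a continuous characteristic, if any."""
        entry = self._active_continuous.get(characteristic)
        return entry[1] if entry is not None else None

    @property
    def at_rest(self) -> bool:
        return not self._effects

    # -- sampling ----------------------------------------------------------

    def advance(self, duration_s: float) -> SignalLog:
        """Generate all channel samples in (t, t + duration]; advance the clock."""
        if duration_s < 0:
            raise SimulationError("cannot advance backwards in time")
        m = self.model
        until = self.t + duration_s
        series = {}
        for i, ch in enumerate(m.channels):
            rate = ch.sampling_rate
            k0 = self._sample_count[i]
            # grid sample times (k+1)/rate with times <= until and > current position
            k1 = int(np.floor(until * rate - 1.0 + 1e-9))
            if k1 < k0:
                series[ch.name] = (np.empty(0), np.empty(0))
                continue
            ks = np.arange(k0, k1 + 1, dtype=np.int64)
            times = (ks + 1.0) / rate
            n = times.size
            values = np.full(n, m.baseline_mu[i])
            if m.noise_sd[i] > 0:
                values += self._noise_rngs[i].normal(0.0, m.noise_sd[i], size=n)
            if m.drift_sd[i] > 0:
                phi = math.exp(-1.0 / (rate * m.drift_tau_s))
                innov_sd = m.drift_sd[i] * math.sqrt(1.0 - phi * phi)
                innov = self._drift_rngs[i].normal(0.0, innov_sd, size=n)
                drift, _ = lfilter([1.0], [1.0, -phi], innov, zi=[phi * self._drift_state[i]])
                self._drift_state[i] = drift[-1]
                values += drift
            for eff in self._effects:
                if eff.shift[i] != 0.0:
                    values += eff.shift[i] * eff.envelope(times, m.latency_s, m.decay_tau_s)
            np.clip(values, m.floor[i], m.ceiling[i], out=values)
            series[ch.name] = (times, values)
            self._sample_count[i] = k1 + 1
        self.t = until
        self._effects = [e for e in self._effects
                         if not e.dead_after(until, m.latency_s, m.decay_tau_s)]
        return SignalLog(series)

    def step(self) -> SignalLog:
        """Advance by one sampling period of the fastest channel."""
        return self.advance(1.0 / float(self.model.channels.sampling_rates.max()))


# -- canonical channel set and profiles -------------------------------------

def default_channels() -> ChannelSet:
    """Four-channel set spanning the cardiac, hemodynamic and sympathetic forms.

    Heart rate variability carries direction -1: it conventionally decreases
    under stress, so its g is sign-flipped before entering the state.
    """
    return ChannelSet([
        Channel("heart_rate", form="cardiac", direction=1, sampling_rate=8.0),
        Channel("hrv_rmssd", form="cardiac", direction=-1, sampling_rate=8.0),
        Channel("systolic_bp", form="hemodynamic", direction=1, sampling_rate=4.0),
        Channel("eda_scl", form="sympathetic", direction=1, sampling_rate=8.0),
    ])


#: Nominal resting parameters: HR (bpm), RMSSD (ms), systolic BP (mmHg), SCL (uS).
_MU = np.array([70.0, 45.0, 120.0, 2.0])
_SIGMA = np.array([5.0, 8.0, 6.0, 0.4])
_FLOOR = np.array([40.0, 3.0, 80.0, 0.05])
_CEILING = np.array([180.0, 150.0, 210.0, 25.0])

#: Full-intensity stress responses (signal units): +HR, -RMSSD, +BP, +SCL.
_MAX_SHIFT = np.array([5.0, -8.0, 4.5, 0.5])


def default_characteristics(seed: int = 0) -> dict[str, CharacteristicSpec]:
    """Three stressor characteristics covering the rule formalism.

    * ``aversive_images`` — continuous, catalog-backed (synthetic valence/
      arousal/dominance ratings; low derived scale = more aversive), presented
      transiently (an image shown for a fixed duration).
    * ``soundscape`` — continuous plain scale 0-10 (5 = neutral ambience,
      10 = harsh/tense, 0 = calming), state-wise.
    * ``realism`` — discrete point-of-view levels, state-wise.
    """
    catalog = make_catalog(60, seed=seed)
    return {
        "aversive_images": CharacteristicSpec(
            "aversive_images", "continuous", catalog=catalog,
            presentation="transient", transient_duration_s=10.0),
        "soundscape": CharacteristicSpec(
            "soundscape", "continuous", scale_range=(0.0, 10.0), presentation="state_wise"),
        "realism": CharacteristicSpec(
            "realism", "discrete", levels=("first_person", "third_person"),
            current_level="first_person", presentation="state_wise"),
    }


def _ground_truth(specs: dict[str, CharacteristicSpec]) -> tuple[dict, dict]:
    continuous: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    level_offsets: dict[str, dict[str, np.ndarray]] = {}
    for name, spec in specs.items():
        if spec.mode == "continuous":
            lo, hi = spec.scale_range
            if name == "aversive_images":
                # most aversive at the low end of the derived scale, neutral at the top
                gamma1 = _MAX_SHIFT / (lo - hi)
                gamma0 = -gamma1 * hi
            else:
                # neutral at mid-scale, full stress response at the top
                mid = 0.5 * (lo + hi)
                gamma1 = _MAX_SHIFT / (hi - mid)
                gamma0 = -gamma1 * mid
            continuous[name] = (gamma0, gamma1)
        else:
            offsets = {lvl: np.zeros(len(_MU)) for lvl in spec.levels}
            # third-person view lowers presence: a mild de-stressor
            offsets[spec.levels[-1]] = -0.4 * _MAX_SHIFT
            level_offsets[name] = offsets
    return continuous, level_offsets


def make_subject(profile: str, seed: int,
                 specs: dict[str, CharacteristicSpec] | None = None) -> SubjectModel:
    """Deterministic subject parameter sets by named profile.

    * ``easy`` — fast, clean responder: noise SD = 0.1 x nominal sigma, no
      drift, wide bounds, latency 0.5 s, tau 0.5 s.
    * ``noisy`` — noise SD = 0.5 x sigma, slower responses (latency 1 s, tau 2 s).
    * ``drifting`` — easy-like noise plus slow wander (stationary SD = 0.3 x
      sigma, 120 s time constant) that the loop must correct for.
    * ``saturating`` — tight ceilings (below the largest ground-truth shift) so
      flooring/ceiling behavior and the selection tie-break path are exercised.
    * ``quadratic`` — easy-like but with a quadratic term in the continuous
      response, deliberately misspecified w.r.t. the linear rule.
    """
    if profile not in PROFILES:
        raise ConfigError(f"unknown subject profile {profile!r}; expected one of {PROFILES}")
    specs = default_characteristics(seed) if specs is None else specs
    continuous, level_offsets = _ground_truth(specs)
    channels = default_channels()
    kw = dict(channels=channels, baseline_mu=_MU.copy(), baseline_sigma=_SIGMA.copy(),
              floor=_FLOOR.copy(), ceiling=_CEILING.copy(),
              continuous_truth=continuous, level_offsets=level_offsets, seed=seed)
    if profile == "easy":
        return SubjectModel(noise_sd=0.1 * _SIGMA, latency_s=0.5, decay_tau_s=0.5, **kw)
    if profile == "noisy":
        return SubjectModel(noise_sd=0.5 * _SIGMA, drift_sd=0.1 * _SIGMA,
                            latency_s=1.0, decay_tau_s=2.0, **kw)
    if profile == "drifting":
        return SubjectModel(noise_sd=0.1 * _SIGMA, drift_sd=0.3 * _SIGMA, drift_tau_s=120.0,
                            latency_s=0.5, decay_tau_s=1.0, **kw)
    if profile == "saturating":
        kw["ceiling"] = _MU + 0.5 * np.abs(_MAX_SHIFT)
        kw["floor"] = _MU - 0.5 * np.abs(_MAX_SHIFT)
        return SubjectModel(noise_sd=0.1 * _SIGMA, latency_s=0.5, decay_tau_s=0.5, **kw)
    # quadratic: mild curvature on the soundscape response
    quad = {"soundscape": 0.02 * _MAX_SHIFT}
    return SubjectModel(noise_sd=0.1 * _SIGMA, latency_s=0.5, decay_tau_s=0.5,
                        quadratic_truth=quad, **kw)


def recovery_report(fitted: FeedbackModel, subject: SubjectModel,
                    baseline: BaselineStats | None = None):
    """Per-coefficient absolute/relative errors of a fitted model vs. ground truth.

    Ground-truth shifts (signal units) are converted to g units with
    ``baseline.sigma`` when a measured session baseline is given (so fitted and
    true coefficients are standardized identically), else with the subject's
    nominal ``baseline_sigma``. Returns (table, median relative error) where
    the table has one row per characteristic/channel/parameter.
    """
    import pandas as pd

    sigma = baseline.sigma if baseline is not None else subject.baseline_sigma
    rows = []
    for name, rule in fitted.rules.items():
        if isinstance(rule, ContinuousRule):
            if name not in subject.continuous_truth:
                raise ReportError(f"subject has no continuous ground truth for {name!r}")
            g0, g1 = subject.continuous_truth[name]
            for label, fit_v, true_v in (("beta0", rule.beta0, g0 / sigma),
                                         ("beta1", rule.beta1, g1 / sigma)):
                for i, ch in enumerate(fitted.channels):
                    rows.append(_error_row(name, ch.name, label, fit_v[i], true_v[i]))
        elif isinstance(rule, DiscreteRule):
            if name not in subject.level_offsets:
                raise ReportError(f"subject has no discrete ground truth for {name!r}")
            for j, tr in enumerate(rule.transitions):
                if not rule.available[j]:
                    continue
                true_col = subject.transition_shift(name, *tr) / sigma
                for i, ch in enumerate(fitted.channels):
                    rows.append(_error_row(name, ch.name, f"D[{tr[0]}>{tr[1]}]",
                                           rule.D[i, j], true_col[i]))
    if not rows:
        raise ReportError("fitted model and subject share no characteristics")
    table = pd.DataFrame(rows)
    median_rel = float(table["rel_err"].median())
    return table, median_rel


def _error_row(char: str, channel: str, param: str, fitted_v: float, true_v: float) -> dict:
    abs_err = abs(fitted_v - true_v)
    rel_err = abs_err / abs(true_v) if true_v != 0 else np.inf if abs_err > 0 else 0.0
    return {"characteristic": char, "channel": channel, "param": param,
            "fitted": float(fitted_v), "truth": float(true_v),
            "abs_err": float(abs_err), "rel_err": float(rel_err)}
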