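"""Fitting condition: calibrate per-subject rules from a predetermined sequence.

The subject is presented with an ordered sequence of stressor adjustments
against a quiet background. Around each adjustment onset the signal log is
windowed — ``pre_window_s`` seconds before as a local baseline, and
``post_window_s`` seconds after as the response — and the per-channel change is
standardized to g units. Grouped observations are then averaged into discrete
transition matrices or regressed (ordinary least squares) into continuous
rules, yielding exactly one rule per characteristic.

Standardization sigma: by default each trial uses its own pre-window SD,
floored at a small fraction of the global session-baseline sigma so a
near-constant pre-window cannot explode g; with ``sigma_source="global"`` the
session baseline SD is used throughout. The post-window mean may skip an
initial ``post_settle_s`` seconds so it measures the settled response rather
than the onset transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .characteristics import Adjustment, CharacteristicSpec
from .errors import DegenerateBaselineError, FittingError, LogIntegrityError, ProtocolError, WindowCoverageError
from .rules import FeedbackModel, ResponseObservation, fit_continuous, fit_discrete
from .session_io import Marker, MarkerLog, adjustment_from_marker, marker_from_adjustment
from .signal_model import BaselineStats, ChannelSet, SignalLog, window_means
from .subject_sim import SubjectSimulator


@dataclass
class FittingProtocol:
    """Ordered adjustment sequence with onsets and window settings."""

    sequence: list[tuple[Adjustment, float]]  # (adjustment, onset_s)
    pre_window_s: float = 10.0
    post_window_s: float = 10.0
    post_settle_s: float = 0.0
    min_trials: int = 1

    def validate(self) -> None:
        if not self.sequence:
            raise ProtocolError("protocol has no adjustments")
        if not (self.pre_window_s > 0 and self.post_window_s > 0):
            raise ProtocolError("windows must be positive")
        if not (0 <= self.post_settle_s < self.post_window_s):
            raise ProtocolError("post_settle_s must lie in [0, post_window_s)")
        onsets = [onset for _, onset in self.sequence]
        gap = self.pre_window_s + self.post_window_s
        for a, b in zip(onsets, onsets[1:]):
            if b <= a:
                raise ProtocolError("onsets must be strictly increasing")
            if b - a < gap:
                raise ProtocolError(
                    f"onsets {a:g}s and {b:g}s closer than pre+post windows ({gap:g}s); "
                    "analysis windows would overlap")

    @property
    def duration_s(self) -> float:
        return self.sequence[-1][1] + self.post_window_s


def build_protocol(specs: dict[str, CharacteristicSpec], *, x_levels: int = 8,
                   repetitions: int = 3, start_s: float = 75.0, spacing_s: float = 25.0,
                   seed: int = 0, pre_window_s: float = 10.0, post_window_s: float = 10.0,
                   post_settle_s: float = 0.0) -> FittingProtocol:
    """Construct a randomized-order fitting sequence covering every characteristic.

    Continuous characteristics are probed at ``x_levels`` evenly spaced values,
    each repeated ``repetitions`` times, presented *transiently* for the length
    of the post window so consecutive trials start from a settled background.
    Discrete characteristics get ``repetitions`` trials per ordered transition,
    presented state-wise along an Eulerian circuit of the transition graph (a
    transition can only be presented from the level the subject is currently
    at), so every ordered transition is visited exactly once per circuit.
    Continuous trials are shuffled and interleaved; the discrete chain order is
    preserved.
    """
    rng = np.random.default_rng(seed)
    continuous_trials: list[Adjustment] = []
    chain: list[Adjustment] = []
    for spec in specs.values():
        if spec.mode == "continuous":
            lo, hi = spec.scale_range
            span = hi - lo
            xs = np.linspace(lo + 0.05 * span, hi - 0.05 * span, x_levels)
            for x in xs:
                for _ in range(repetitions):
                    continuous_trials.append(Adjustment(
                        spec.name, value=float(x),
                        presentation="transient", duration_s=post_window_s))
        else:
            circuit = _eulerian_circuit(spec.levels, spec.current_level)
            for _ in range(repetitions):
                for frm, to in circuit:
                    chain.append(Adjustment(spec.name, from_level=frm, to_level=to,
                                            presentation="state_wise"))
    order = list(rng.permutation(len(continuous_trials)))
    slots = sorted(rng.choice(len(order) + len(chain), size=len(chain), replace=False))
    trials: list[Adjustment] = []
    for k in range(len(order) + len(chain)):
        if slots and k == slots[0]:
            trials.append(chain.pop(0))
            slots.pop(0)
        else:
            trials.append(continuous_trials[order.pop(0)])
    sequence = [(adj, start_s + k * spacing_s) for k, adj in enumerate(trials)]
    return FittingProtocol(sequence, pre_window_s=pre_window_s, post_window_s=post_window_s,
                           post_settle_s=post_settle_s)


def _eulerian_circuit(levels: tuple[str, ...], start: str) -> list[tuple[str, str]]:
    """Closed walk over all ordered level pairs, each traversed exactly once.

    The complete digraph on the levels is Eulerian (in-degree = out-degree =
    L - 1 at every node), so Hierholzer's algorithm always succeeds.
    """
    remaining: dict[str, list[str]] = {a: [b for b in levels if b != a] for a in levels}
    stack, walk = [start], []
    while stack:
        v = stack[-1]
        if remaining[v]:
            stack.append(remaining[v].pop(0))
        else:
            walk.append(stack.pop())
    walk.reverse()
    return list(zip(walk, walk[1:]))


@dataclass
class FittingResult:
    model: FeedbackModel
    observations: dict[str, list[ResponseObservation]]
    diagnostics: dict = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    baseline: BaselineStats | None = None
    log: SignalLog | None = None
    markers: MarkerLog | None = None


def extract_responses(log: SignalLog, markers: MarkerLog, channels: ChannelSet, *,
                      pre_s: float = 10.0, post_s: float = 10.0, post_settle_s: float = 0.0,
                      sigma_source: str = "pre", global_baseline: BaselineStats | None = None,
                      sigma_floor_frac: float = 1e-6,
                      known_specs: set[str] | None = None):
    """Windowed per-channel responses in g units for every adjustment marker.

    Returns (observations, dropped) where ``dropped`` records trials whose
    windows were not covered (the trial is dropped, never imputed).
    """
    if sigma_source not in ("pre", "global"):
        raise ValueError("sigma_source must be 'pre' or 'global'")
    if sigma_source == "global" and global_baseline is None:
        raise DegenerateBaselineError("sigma_source='global' requires a session baseline")
    if global_baseline is not None and np.any(global_baseline.sigma <= 0):
        raise DegenerateBaselineError("global baseline sigma of 0 cannot standardize")
    observations: list[ResponseObservation] = []
    dropped: list[str] = []
    trial = 0
    for marker in markers:
        if marker.kind != "adjustment":
            continue
        if known_specs is not None and marker.characteristic not in known_specs:
            raise LogIntegrityError(
                f"marker at t={marker.timestamp_s:g}s references unknown "
                f"characteristic {marker.characteristic!r}")
        adj = adjustment_from_marker(marker)
        try:
            pre, post_mu = window_means(log, channels, marker.timestamp_s, pre_s, post_s,
                                        post_settle_s=post_settle_s)
        except (WindowCoverageError, KeyError) as exc:
            dropped.append(f"t={marker.timestamp_s:g}s {marker.characteristic}: {exc}")
            continue
        if sigma_source == "global":
            sigma = global_baseline.sigma
        else:
            sigma = pre.sigma.copy()
            if global_baseline is not None:
                sigma = np.maximum(sigma, sigma_floor_frac * global_baseline.sigma)
            if np.any(sigma <= 0):
                raise DegenerateBaselineError(
                    "pre-window sigma is 0 and no global baseline is available to floor it")
        delta_g = (post_mu - pre.mu) / sigma
        observations.append(ResponseObservation(
            characteristic=adj.characteristic, delta_g=delta_g,
            transition=adj.transition if adj.is_discrete else None,
            x=None if adj.is_discrete else adj.value, trial_index=trial))
        trial += 1
    return observations, dropped


def run_fitting(protocol: FittingProtocol, source, channels: ChannelSet,
                specs: dict[str, CharacteristicSpec], *, weights=None,
                global_baseline: BaselineStats | None = None,
                baseline_duration_s: float = 60.0, sigma_source: str = "pre",
                sigma_floor_frac: float = 1e-6, fitted_from: str = "fitting-session") -> FittingResult:
    """Execute the fitting condition and fit one rule per characteristic.

    ``source`` is either a :class:`SubjectSimulator` (the protocol is presented
    to it, markers written as it goes) or a recorded ``(SignalLog, MarkerLog)``
    pair. Trials with window-coverage failures are dropped and reported;
    characteristics with no usable trials are flagged and excluded from the
    model.
    """
    protocol.validate()
    weights = np.ones(len(channels)) if weights is None else np.asarray(weights, dtype=float)

    if isinstance(source, SubjectSimulator):
        log, markers, global_baseline = _present_protocol(
            protocol, source, channels, global_baseline, baseline_duration_s)
    else:
        log, markers = source
        first_onset = protocol.sequence[0][1]
        if log.t_max < protocol.duration_s - 1e-9 or first_onset < protocol.pre_window_s:
            raise ProtocolError("signal log does not cover the full protocol duration")

    observations, dropped = extract_responses(
        log, markers, channels, pre_s=protocol.pre_window_s, post_s=protocol.post_window_s,
        post_settle_s=protocol.post_settle_s, sigma_source=sigma_source,
        global_baseline=global_baseline, sigma_floor_frac=sigma_floor_frac,
        known_specs=set(specs))
    if not observations:
        raise FittingError("no usable trials: every window failed coverage")

    grouped: dict[str, list[ResponseObservation]] = {}
    for obs in observations:
        grouped.setdefault(obs.characteristic, []).append(obs)

    rules = {}
    diagnostics: dict[str, dict] = {}
    flagged: list[str] = []
    for name, spec in specs.items():
        obs = grouped.get(name, [])
        diag = {"n_trials": len(obs)}
        if len(obs) < max(1, protocol.min_trials):
            flagged.append(name)
            diag["flag"] = "insufficient trials; excluded from model"
            diagnostics[name] = diag
            continue
        if spec.mode == "discrete":
            rule = fit_discrete(obs, spec.transitions(), len(channels))
            resid = [o.delta_g - rule.D[:, rule.column(o.transition)] for o in obs]
        else:
            rule = fit_continuous(obs, spec.scale_range)
            resid = [o.delta_g - (rule.beta0 + rule.beta1 * o.x) for o in obs]
        diag["residual_rms"] = float(np.sqrt(np.mean(np.square(resid))))
        rules[name] = rule
        diagnostics[name] = diag

    model = FeedbackModel(channels=channels, weights=weights, rules=rules, fitted_from=fitted_from)
    diagnostics["_dropped_trials"] = len(dropped)
    diagnostics["_flagged"] = flagged
    return FittingResult(model=model, observations=grouped, diagnostics=diagnostics,
                         dropped=dropped, baseline=global_baseline, log=log, markers=markers)


def _present_protocol(protocol: FittingProtocol, sim: SubjectSimulator, channels: ChannelSet,
                      global_baseline: BaselineStats | None, baseline_duration_s: float):
    """Drive a simulator through the protocol, collecting log + markers."""
    from .controller import baseline_measurement  # local import to avoid a cycle

    chunks: list[SignalLog] = []
    markers = MarkerLog()
    if global_baseline is None:
        if sim.t > 0 or not sim.at_rest:
            raise ProtocolError("baseline must be measured at rest before the protocol")
        markers.append(Marker(sim.t, "baseline_start"))
        global_baseline, rest = baseline_measurement(sim, baseline_duration_s, return_log=True)
        chunks.append(rest)
        markers.append(Marker(sim.t, "baseline_end"))
    for adj, onset in protocol.sequence:
        if onset - protocol.pre_window_s < sim.t - 1e-9:
            raise ProtocolError(f"onset {onset:g}s leaves no room for its pre-window")
        chunks.append(sim.advance(onset - sim.t))
        sim.apply(adj, onset)
        markers.append(marker_from_adjustment(adj, onset))
        chunks.append(sim.advance(protocol.post_window_s))
    log = SignalLog.concat(chunks)
    return log, markers, global_baseline
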