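"""The closed biocybernetic loop.

Every loop period the controller (1) windows the most recent samples and
estimates the current state s_c against the session baseline, (2) builds the
candidate set — for each discrete rule, every available transition leaving the
characteristic's current level; for each continuous rule, the single adjustment
value obtained by inverting the rule toward the target — (3) selects the
candidate whose predicted state is closest to the desired state s_d,

    argmin over candidates of |s_d - (s_c + delta_hat)|,

with a two-stage tie-break: among tied candidates, prefer the one with the
largest predicted effect on the channel whose g currently sits farthest from
the target (this steers activity away from channels near their floor/ceiling),
then characteristic name and payload order for full determinism. Exactly one
adjustment is applied per iteration (or an explicit no-action recorded), and
because the loop runs continuously, state changes not caused by the controller
(drift, spontaneous shifts) are measured and corrected for on the next period.

For state-wise continuous characteristics the inversion accounts for the
predicted contribution of the currently applied value: the rule predicts the
response to a value relative to neutral, so the desired *change* from the
current setting is (s_d - s_c) + predicted current contribution. Without this
correction a persistent actuator alternates between target and rest. The
``account_current=False`` switch restores the plain inversion of (s_d - s_c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .characteristics import (
    Adjustment,
    CharacteristicSpec,
    nearest_stimulus,
    stimulus_scale,
)
from .errors import ControllerError, ProtocolError, WindowCoverageError
from .rules import (
    ContinuousRule,
    DiscreteRule,
    FeedbackModel,
    invert_continuous,
    predict_continuous,
    predict_discrete,
)
from .session_io import Marker, MarkerLog, marker_from_adjustment
from .signal_model import BaselineStats, SignalLog, activity_state, hedges_g_vector
from .subject_sim import SubjectSimulator


@dataclass
class CandidatePrediction:
    """One applicable adjustment with its predicted effect on the state."""

    characteristic: str
    adjustment: Adjustment
    delta_hat: float
    predicted_state: float
    delta_g_hat: np.ndarray

    def __post_init__(self) -> None:
        self.delta_g_hat = np.asarray(self.delta_g_hat, dtype=float)


@dataclass
class SessionLog:
    """One row per loop iteration; timestamps strictly increasing."""

    frame: pd.DataFrame
    period_s: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frame) > 1:
            t = self.frame["t"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ControllerError("session log timestamps must be strictly increasing")


def baseline_measurement(sim: SubjectSimulator, duration_s: float, *,
                         min_duration_s: float = 60.0, sigma_floor: float = 1e-12,
                         return_log: bool = False):
    """Measure the resting baseline: per-channel mean and SD at rest.

    The subject must be at rest (no adjustment applied so far); measuring with
    an active stressor is a protocol error. A zero SD (noise-free stream) is
    floored at ``sigma_floor`` so the stats stay usable; callers that know the
    nominal sigma should supply their own :class:`BaselineStats` instead.
    """
    if duration_s < min_duration_s:
        raise ProtocolError(f"baseline of {duration_s:g}s is shorter than the "
                            f"required minimum {min_duration_s:g}s")
    if not sim.at_rest:
        raise ProtocolError("an adjustment is active; baseline must be measured at rest")
    chunk = sim.advance(duration_s)
    channels = sim.model.channels
    mu = np.empty(len(channels))
    sd = np.empty(len(channels))
    n = np.empty(len(channels), dtype=int)
    for i, ch in enumerate(channels):
        _, v = chunk.channel(ch.name)
        if v.size < 2:
            raise ProtocolError(f"channel {ch.name!r}: baseline captured fewer than 2 samples")
        mu[i], sd[i], n[i] = v.mean(), v.std(ddof=1), v.size
    stats = BaselineStats(channels, mu, np.maximum(sd, sigma_floor), n, duration_s)
    return (stats, chunk) if return_log else stats


def candidate_set(model: FeedbackModel, specs: dict[str, CharacteristicSpec],
                  s_c: float, s_d: float, *, current_levels: dict[str, str] | None = None,
                  current_x: dict[str, float] | None = None, account_current: bool = True,
                  epsilon: float = 1e-8) -> list[CandidatePrediction]:
    """All applicable rule adjustments with their predicted state changes.

    Discrete rules contribute one candidate per available transition leaving
    the characteristic's current level. Continuous rules contribute the single
    candidate at the inverted value (clamped to the domain and snapped to the
    nearest catalog stimulus when catalog-backed); a non-invertible rule
    (aggregate slope below ``epsilon``) contributes the domain endpoint whose
    predicted state lies closest to the target instead of crashing.
    """
    if not model.rules:
        raise ControllerError("feedback model contains no rules")
    w, dirs = model.weights, model.directions
    current_levels = current_levels or {}
    current_x = current_x or {}
    candidates: list[CandidatePrediction] = []
    for name in sorted(model.rules):
        rule = model.rules[name]
        spec = specs[name]
        if isinstance(rule, DiscreteRule):
            level = current_levels.get(name, spec.current_level)
            for j, (frm, to) in enumerate(rule.transitions):
                if frm != level or not rule.available[j]:
                    continue
                delta = predict_discrete(rule, j, w, dirs)
                adj = Adjustment(name, from_level=frm, to_level=to,
                                 presentation=spec.presentation,
                                 duration_s=spec.transient_duration_s)
                candidates.append(CandidatePrediction(name, adj, delta, s_c + delta,
                                                      rule.D[:, j].copy()))
        else:
            x_cur = current_x.get(name)
            contrib = 0.0
            chan_cur = np.zeros(len(model.channels))
            if account_current and x_cur is not None:
                contrib = predict_continuous(rule, x_cur, w, dirs)
                chan_cur = rule.beta0 + rule.beta1 * x_cur
            x = invert_continuous(rule, (s_d - s_c) + contrib, w, dirs, epsilon=epsilon)
            if x is None:
                # non-invertible (flat) rule: fall back to the domain endpoint whose
                # predicted state is closest to the target; a fully null rule (no
                # predicted change anywhere) contributes no candidate at all
                lo, hi = rule.domain
                best = min((lo, hi), key=lambda e: abs(
                    s_d - (s_c + predict_continuous(rule, e, w, dirs) - contrib)))
                if abs(predict_continuous(rule, best, w, dirs) - contrib) < epsilon:
                    continue
                x = float(best)
            stim = None
            if spec.catalog is not None:
                stim = nearest_stimulus(spec.catalog, x)
                x = stimulus_scale(spec.catalog, stim)
            delta = predict_continuous(rule, x, w, dirs) - contrib
            adj = Adjustment(name, value=x, stimulus_id=stim,
                             presentation=spec.presentation,
                             duration_s=spec.transient_duration_s)
            candidates.append(CandidatePrediction(name, adj, delta, s_c + delta,
                                                  (rule.beta0 + rule.beta1 * x) - chan_cur))
    return candidates


def select_rule(candidates: list[CandidatePrediction], s_c: float, s_d: float,
                g: np.ndarray, tie_tol: float = 1e-9) -> CandidatePrediction | None:
    """Pick the candidate whose predicted state is closest to the target.

    Returns None on an empty candidate list (the loop idles one period). Ties
    within ``tie_tol`` are resolved toward the candidate with the largest
    predicted effect on the channel whose current g lies farthest from s_d,
    then by characteristic name and payload order.
    """
    if not candidates:
        return None
    g = np.asarray(g, dtype=float)
    errs = np.array([abs(s_d - c.predicted_state) for c in candidates])
    best = errs.min()
    tied = [c for c, e in zip(candidates, errs) if e <= best + tie_tol]
    if len(tied) == 1:
        return tied[0]
    k = int(np.argmax(np.abs(s_d - g)))
    tied.sort(key=lambda c: (-abs(c.delta_g_hat[k]), c.characteristic,
                             c.adjustment.payload_str()))
    return tied[0]


def _desired_at(desired, t: float) -> float:
    """Constant target or piecewise-constant trajectory [(t0, v0), (t1, v1), ...]."""
    if np.isscalar(desired):
        return float(desired)
    value = float(desired[0][1])
    for t_k, v_k in desired:
        if t >= t_k:
            value = float(v_k)
    return value


def control_loop(model: FeedbackModel, sim: SubjectSimulator,
                 specs: dict[str, CharacteristicSpec], desired, duration_s: float, *,
                 period_s: float = 5.0, state_window_s: float = 2.5,
                 baseline: BaselineStats | None = None, baseline_duration_s: float = 60.0,
                 min_baseline_s: float = 60.0, refractory_s: float = 0.0,
                 enabled: bool = True, account_current: bool = True,
                 epsilon: float = 1e-8) -> tuple[SessionLog, SignalLog, MarkerLog]:
    """Run the closed loop for ``duration_s`` seconds of simulated time.

    Each period: advance the subject, estimate g and s_c from the most recent
    ``state_window_s`` seconds against the session baseline, build candidates,
    select one adjustment, apply it (marker written) and log the step. With
    ``enabled=False`` the subject runs uncontrolled on the same schedule — the
    matched no-control comparison. Window dropout (too few samples) is logged
    as a gap and the loop continues with the last valid state.
    """
    if period_s < state_window_s:
        raise ControllerError("loop period must cover the state-estimation window")
    if enabled and not model.rules:
        raise ControllerError("cannot control with an empty feedback model")
    markers = MarkerLog()
    if baseline is None:
        markers.append(Marker(sim.t, "baseline_start"))
        baseline, _ = baseline_measurement(sim, baseline_duration_s,
                                           min_duration_s=min_baseline_s, return_log=True)
        markers.append(Marker(sim.t, "baseline_end"))
    channels = model.channels
    names = channels.names
    markers.append(Marker(sim.t, "loop_start"))
    n_iter = int(round(duration_s / period_s))
    all_chunks: list[SignalLog] = []
    chunks: list[SignalLog] = []
    keep = max(2, int(np.ceil(state_window_s / period_s)) + 1)
    rows: list[dict] = []
    g = np.zeros(len(channels))
    s_c = 0.0
    last_action_t = -np.inf
    for _ in range(n_iter):
        chunk = sim.advance(period_s)
        all_chunks.append(chunk)
        chunks = (chunks + [chunk])[-keep:]
        recent = SignalLog.concat(chunks)
        t_now = sim.t
        gap = False
        try:
            means = np.empty(len(channels))
            for i, ch in enumerate(channels):
                t_arr, v = recent.channel(ch.name)
                mask = (t_arr >= t_now - state_window_s) & (t_arr <= t_now)
                if mask.sum() < 2:
                    raise WindowCoverageError(ch.name)
                means[i] = v[mask].mean()
            g = hedges_g_vector(means, baseline)
            s_c = activity_state(g, model.weights, channels.directions)
        except WindowCoverageError:
            gap = True  # signal dropout: keep last valid state
        s_d = _desired_at(desired, t_now)
        row = {"t": t_now, "s_c": s_c, "s_d": s_d}
        for i, name in enumerate(names):
            row[f"g_{name}"] = g[i]
        chosen = None
        if enabled and not gap and t_now - last_action_t >= refractory_s:
            candidates = candidate_set(
                model, specs, s_c, s_d, current_levels=dict(sim.current_levels),
                current_x={n: sim.active_continuous_value(n) for n in model.rules
                           if sim.active_continuous_value(n) is not None},
                account_current=account_current, epsilon=epsilon)
            chosen = select_rule(candidates, s_c, s_d, g)
        if chosen is not None:
            sim.apply(chosen.adjustment, t_now)
            markers.append(marker_from_adjustment(chosen.adjustment, t_now))
            last_action_t = t_now
            row.update(action=chosen.adjustment.payload_str(),
                       characteristic=chosen.characteristic,
                       delta_hat=chosen.delta_hat, predicted_state=chosen.predicted_state)
        else:
            row.update(action="none", characteristic="",
                       delta_hat=np.nan, predicted_state=np.nan)
        row["gap"] = gap
        rows.append(row)
    markers.append(Marker(sim.t, "loop_end"))
    frame = pd.DataFrame(rows)
    # realized state change of each step, observable one period later
    frame["realized_delta"] = frame["s_c"].shift(-1) - frame["s_c"]
    session = SessionLog(frame=frame, period_s=period_s,
                         provenance={"enabled": enabled, "duration_s": duration_s,
                                     "state_window_s": state_window_s,
                                     "subject_seed": int(sim.model.seed)})
    return session, SignalLog.concat(all_chunks), markers
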