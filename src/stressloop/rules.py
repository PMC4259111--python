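"""Feedback-model rules: per-characteristic predictors of response change.

A *discrete* rule for a characteristic with L levels is a matrix D with one row
per channel and one column per ordered level transition (L*(L-1) columns):
entry D[i, j] is the predicted change in channel i's g when transition j is
applied. A *continuous* rule is a simple linear regression per channel,
predicted change = beta0_i + beta1_i * x, over the characteristic's scale.

Both rule kinds predict a scalar state change by the weighted average of the
per-channel predictions (direction-adjusted), so discrete and continuous
predictions are commensurate with the state p_c and can compete in the
controller's argmin. A ``strict_paper`` switch restores the literal
unnormalized discrete summation sum_i(D_ij * w_i) for comparison.

Fitting: discrete columns are arithmetic means of observed per-channel deltas
over repeated trials of the same transition; continuous coefficients are the
ordinary least-squares minimizers of the per-channel residual sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .characteristics import Adjustment, clamp_to_range
from .errors import FittingError, InvalidWeightsError, RankDeficiencyError
from .signal_model import ChannelSet, validate_weights


@dataclass
class ResponseObservation:
    """One measured trial: the adjustment applied and the per-channel change in g."""

    characteristic: str
    delta_g: np.ndarray
    transition: tuple[str, str] | None = None
    x: float | None = None
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.delta_g = np.asarray(self.delta_g, dtype=float)
        if (self.transition is None) == (self.x is None):
            raise FittingError("observation must carry either a transition or an x value")


@dataclass
class DiscreteRule:
    """Transition-matrix rule: D has |channels| rows, L*(L-1) columns."""

    characteristic: str
    transitions: list[tuple[str, str]]
    D: np.ndarray
    available: np.ndarray | None = None  # per-column: had >= 1 observation

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2 or self.D.shape[1] != len(self.transitions):
            raise ValueError("D must be (n_channels, n_transitions)")
        if self.available is None:
            self.available = np.ones(self.D.shape[1], dtype=bool)
        self.available = np.asarray(self.available, dtype=bool)
        if not np.all(np.isfinite(self.D[:, self.available])):
            raise ValueError("available D columns must be finite")

    @property
    def kind(self) -> str:
        return "discrete"

    def column(self, transition: tuple[str, str]) -> int:
        try:
            return self.transitions.index(tuple(transition))
        except ValueError:
            raise IndexError(f"unknown transition {transition}") from None


@dataclass
class ContinuousRule:
    """Per-channel linear rule: predicted delta g_i = beta0_i + beta1_i * x over ``domain``."""

    characteristic: str
    beta0: np.ndarray
    beta1: np.ndarray
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.beta1 = np.asarray(self.beta1, dtype=float)
        if self.beta0.shape != self.beta1.shape or self.beta0.ndim != 1:
            raise ValueError("beta0/beta1 must be aligned 1-d arrays")
        if not (np.all(np.isfinite(self.beta0)) and np.all(np.isfinite(self.beta1))):
            raise ValueError("rule coefficients must be finite")
        if not self.domain[0] < self.domain[1]:
            raise ValueError("domain must satisfy x_min < x_max")

    @property
    def kind(self) -> str:
        return "continuous"


Rule = DiscreteRule | ContinuousRule


def _weighted_combination(per_channel: np.ndarray, w: np.ndarray, directions, normalize: bool) -> float:
    w = validate_weights(w)
    if per_channel.shape != w.shape:
        raise InvalidWeightsError("rule channel count must match weights")
    d = np.ones_like(w) if directions is None else np.asarray(directions, dtype=float)
    total = float(np.sum(d * per_channel * w))
    return total / float(np.sum(w)) if normalize else total


def predict_discrete(rule: DiscreteRule, j: int, w, directions=None, *, strict_paper: bool = False) -> float:
    """Predicted state change for transition column j (weighted average over channels)."""
    if not (0 <= j < rule.D.shape[1]):
        raise IndexError(f"transition column {j} out of range")
    return _weighted_combination(rule.D[:, j], np.asarray(w, dtype=float), directions,
                                 normalize=not strict_paper)


def predict_continuous(rule: ContinuousRule, x: float, w, directions=None) -> float:
    """Predicted state change for adjustment value x (affine in x)."""
    x = clamp_to_range(float(x), rule.domain)
    per_channel = rule.beta0 + rule.beta1 * x
    return _weighted_combination(per_channel, np.asarray(w, dtype=float), directions, normalize=True)


def aggregate_coefficients(rule: ContinuousRule, w, directions=None) -> tuple[float, float]:
    """Intercept/slope of the aggregated state prediction: delta_s(x) = a + b*x."""
    w = validate_weights(np.asarray(w, dtype=float))
    d = np.ones_like(w) if directions is None else np.asarray(directions, dtype=float)
    a = float(np.sum(d * rule.beta0 * w) / np.sum(w))
    b = float(np.sum(d * rule.beta1 * w) / np.sum(w))
    return a, b


def invert_continuous(rule: ContinuousRule, delta_desired: float, w, directions=None,
                      epsilon: float = 1e-8) -> float | None:
    """Adjustment value predicted to produce the desired state change.

    Solves a + b*x = delta_desired for the aggregated coefficients and clamps
    to the rule domain; the predict/invert round trip is exact whenever the
    solution is interior. Returns None when |b| < epsilon (non-invertible rule,
    to be excluded or endpoint-handled by the caller rather than crash).
    """
    a, b = aggregate_coefficients(rule, w, directions)
    if abs(b) < epsilon:
        return None
    return clamp_to_range((float(delta_desired) - a) / b, rule.domain)


def predicted_channel_deltas(rule: Rule, *, j: int | None = None, x: float | None = None) -> np.ndarray:
    """Per-channel predicted delta g for one concrete adjustment of the rule."""
    if isinstance(rule, DiscreteRule):
        return rule.D[:, j].copy()
    return rule.beta0 + rule.beta1 * float(x)


def fit_discrete(observations: list[ResponseObservation], transitions: list[tuple[str, str]],
                 n_channels: int) -> DiscreteRule:
    """Average observed per-channel deltas per transition into a rule matrix.

    Repeated trials of the same transition are aggregated by the arithmetic
    mean. Transitions never observed are flagged unavailable (NaN column) and
    excluded from candidate search rather than imputed.
    """
    obs = [o for o in observations if o.transition is not None]
    if not obs:
        raise FittingError("no discrete observations to fit")
    name = obs[0].characteristic
    D = np.full((n_channels, len(transitions)), np.nan)
    available = np.zeros(len(transitions), dtype=bool)
    index = {tuple(tr): j for j, tr in enumerate(transitions)}
    groups: dict[int, list[np.ndarray]] = {}
    for o in obs:
        if o.delta_g.shape != (n_channels,):
            raise FittingError("observation delta_g must align with the channel set")
        j = index.get(tuple(o.transition))
        if j is None:
            raise FittingError(f"observation transition {o.transition} not in transition list")
        groups.setdefault(j, []).append(o.delta_g)
    for j, rows in groups.items():
        D[:, j] = np.mean(rows, axis=0)
        available[j] = True
    return DiscreteRule(name, list(map(tuple, transitions)), D, available)


def fit_continuous(observations: list[ResponseObservation], domain: tuple[float, float]) -> ContinuousRule:
    """Per-channel ordinary least squares of delta g on the adjustment value x."""
    obs = [o for o in observations if o.x is not None]
    if len(obs) < 2:
        raise FittingError("continuous fitting needs >= 2 observations")
    name = obs[0].characteristic
    x = np.array([o.x for o in obs], dtype=float)
    if np.ptp(x) == 0:
        raise RankDeficiencyError("all adjustment values identical; slope is unidentifiable")
    Y = np.stack([o.delta_g for o in obs])  # (n_trials, n_channels)
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    return ContinuousRule(name, beta0=coef[0], beta1=coef[1], domain=tuple(map(float, domain)))


@dataclass
class FeedbackModel:
    """Exactly one fitted rule per enabled characteristic, plus channel weights."""

    channels: ChannelSet
    weights: np.ndarray
    rules: dict[str, Rule] = field(default_factory=dict)
    fitted_from: str = ""

    def __post_init__(self) -> None:
        self.weights = validate_weights(self.weights)
        if self.weights.shape != (len(self.channels),):
            raise InvalidWeightsError("one weight per channel required")
        for name, rule in self.rules.items():
            if name != rule.characteristic:
                raise ValueError(f"rule registered under {name!r} models {rule.characteristic!r}")
            n = rule.D.shape[0] if isinstance(rule, DiscreteRule) else rule.beta0.shape[0]
            if n != len(self.channels):
                raise ValueError(f"rule {name!r} channel count does not match the channel set")

    @property
    def directions(self) -> np.ndarray:
        return self.channels.directions

    def predict(self, characteristic: str, *, j: int | None = None, x: float | None = None,
                strict_paper: bool = False) -> float:
        rule = self.rules[characteristic]
        if isinstance(rule, DiscreteRule):
            return predict_discrete(rule, j, self.weights, self.directions, strict_paper=strict_paper)
        return predict_continuous(rule, x, self.weights, self.directions)

    def predict_adjustment(self, adj: Adjustment) -> float:
        rule = self.rules[adj.characteristic]
        if isinstance(rule, DiscreteRule):
            return predict_discrete(rule, rule.column(adj.transition), self.weights, self.directions)
        return predict_continuous(rule, adj.value, self.weights, self.directions)
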