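"""Core stress-state algebra.

A subject's momentary *physiological activity state* is a weighted average of
per-channel standardized responses. Each channel (heart rate, heart rate
variability, blood pressure, electrodermal activity, ...) is standardized
against a resting baseline as a standardized mean difference,

    g = (mu_response - mu_baseline) / sigma_baseline   (Hedges' g),

so a value of ``g = 1`` means the channel currently sits one baseline standard
deviation above rest. The scalar state is

    p_c = sum_i(d_i * g_i * w_i) / sum_i(w_i),

with non-negative weights ``w`` (default all 1) and per-channel direction signs
``d`` in {+1, -1}. Directions let channels that conventionally *decrease* under
stress (e.g. heart rate variability) contribute with the right sign; the
default +1 keeps the plain weighted summation. The current state estimate s_c
is taken to be p_c (identity estimator).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateBaselineError,
    InvalidWeightsError,
    WindowCoverageError,
)

CHANNEL_FORMS = ("cardiac", "hemodynamic", "sympathetic")


@dataclass(frozen=True)
class Channel:
    """One measured stress-response type.

    Parameters
    ----------
    name:
        Unique identifier within a :class:`ChannelSet`.
    form:
        Response system the channel originates from: ``cardiac``,
        ``hemodynamic`` or ``sympathetic``.
    direction:
        Sign (+1 or -1) applied to the channel's g before combination. Use -1
        for channels that drop under stress so that positive state means
        "more stressed" on every channel.
    sampling_rate:
        Samples per second of the derived-value stream (> 0).
    """

    name: str
    form: str = "cardiac"
    direction: int = 1
    sampling_rate: float = 8.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("channel name must be non-empty")
        if self.form not in CHANNEL_FORMS:
            raise ValueError(f"unknown channel form {self.form!r}; expected one of {CHANNEL_FORMS}")
        if self.direction not in (1, -1):
            raise ValueError("channel direction must be +1 or -1")
        if not (self.sampling_rate > 0 and np.isfinite(self.sampling_rate)):
            raise ValueError("sampling_rate must be a positive finite number")


class ChannelSet(Sequence):
    """Ordered collection of uniquely named channels."""

    def __init__(self, channels: Iterable[Channel]):
        chans = tuple(channels)
        names = [c.name for c in chans]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if not chans:
            raise ValueError("a ChannelSet needs at least one channel")
        self._channels = chans
        self._index = {c.name: i for i, c in enumerate(chans)}

    def __len__(self) -> int:
        return len(self._channels)

    def __getitem__(self, i):
        return self._channels[i]

    def __iter__(self):
        return iter(self._channels)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChannelSet) and self._channels == other._channels

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self._channels)

    @property
    def directions(self) -> np.ndarray:
        return np.array([c.direction for c in self._channels], dtype=float)

    @property
    def sampling_rates(self) -> np.ndarray:
        return np.array([c.sampling_rate for c in self._channels], dtype=float)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown channel {name!r}") from None


@dataclass
class BaselineStats:
    """Per-channel resting statistics (mu, sigma) of a baseline measurement.

    ``sigma`` may be 0 at construction (a constant stream has zero spread);
    any operation that *standardizes* by sigma raises
    :class:`DegenerateBaselineError` when sigma <= 0.
    """

    channels: ChannelSet
    mu: np.ndarray
    sigma: np.ndarray
    n_samples: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=int)
        n = len(self.channels)
        for arr, label in ((self.mu, "mu"), (self.sigma, "sigma"), (self.n_samples, "n_samples")):
            if arr.shape != (n,):
                raise ValueError(f"{label} must have one entry per channel")
        if not np.all(np.isfinite(self.mu)) or not np.all(np.isfinite(self.sigma)):
            raise ValueError("baseline statistics must be finite")
        if np.any(self.sigma < 0):
            raise ValueError("baseline sigma cannot be negative")
        if np.any(self.n_samples < 2):
            raise ValueError("baseline needs at least 2 samples per channel")


@dataclass(frozen=True)
class StressState:
    """Scalar state estimate: current s_c, desired s_d, both in weighted-average-SD units."""

    current: float
    desired: float
    timestamp: float

    def __post_init__(self) -> None:
        for v in (self.current, self.desired, self.timestamp):
            if not np.isfinite(v):
                raise ValueError("stress state fields must be finite")

    @property
    def error(self) -> float:
        """Absolute distance to target, |s_d - s_c|."""
        return abs(self.desired - self.current)


def hedges_g(stress_mean, mu, sigma):
    """Standardized mean difference (mu_response - mu_baseline) / sigma_baseline.

    Accepts scalars or aligned arrays. Positive iff the response mean exceeds
    the baseline mean. Raises :class:`DegenerateBaselineError` if any sigma is
    <= 0 or any input is non-finite.
    """
    stress_mean = np.asarray(stress_mean, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if not (np.all(np.isfinite(stress_mean)) and np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))):
        raise DegenerateBaselineError("non-finite input to hedges_g")
    if np.any(sigma <= 0):
        raise DegenerateBaselineError("baseline sigma must be > 0 to standardize")
    out = (stress_mean - mu) / sigma
    return float(out) if out.ndim == 0 else out


def hedges_g_vector(stress_means, baseline: BaselineStats) -> np.ndarray:
    """Per-channel g against a session baseline."""
    return np.atleast_1d(hedges_g(stress_means, baseline.mu, baseline.sigma))


def validate_weights(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or not np.all(np.isfinite(w)) or np.any(w < 0) or not np.any(w > 0):
        raise InvalidWeightsError("weights must be finite, non-negative, with at least one > 0")
    return w


def normalize_weights(w) -> np.ndarray:
    """Scale weights to sum to one."""
    w = validate_weights(w)
    return w / w.sum()


def activity_state(g, w, directions=None) -> float:
    """Weighted average of (direction-adjusted) per-channel g: the scalar p_c.

    With unit weights and all +1 directions this is the plain mean of g.
    """
    g = np.asarray(g, dtype=float)
    w = validate_weights(w)
    if g.shape != w.shape:
        raise InvalidWeightsError("g and weights must align on channels")
    if directions is None:
        directions = np.ones_like(g)
    d = np.asarray(directions, dtype=float)
    if d.shape != g.shape:
        raise InvalidWeightsError("directions must align on channels")
    return float(np.sum(d * g * w) / np.sum(w))


def estimate_stress_state(p_c: float, timestamp: float, desired: float) -> StressState:
    """Identity estimator: the current stress state s_c is taken to be p_c."""
    return StressState(current=float(p_c), desired=float(desired), timestamp=float(timestamp))


class SignalLog:
    """Multi-channel timestamped sample log.

    Stored per channel as (timestamps, values) float arrays, timestamps
    ascending within each channel. Timestamps are seconds from session start.
    """

    def __init__(self, series: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, (t, v) in series.items():
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            if t.shape != v.shape or t.ndim != 1:
                raise ValueError(f"channel {name!r}: timestamps and values must be aligned 1-d arrays")
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ValueError(f"channel {name!r}: timestamps must be ascending")
            self._series[name] = (t, v)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self._series)

    def channel(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self._series[name]
        except KeyError:
            raise KeyError(f"log has no channel {name!r}") from None

    def __len__(self) -> int:
        return sum(t.size for t, _ in self._series.values())

    @property
    def t_max(self) -> float:
        ends = [t[-1] for t, _ in self._series.values() if t.size]
        return max(ends) if ends else float("-inf")

    @staticmethod
    def concat(logs: Sequence["SignalLog"]) -> "SignalLog":
        names: list[str] = []
        for log in logs:
            for n in log.channel_names:
                if n not in names:
                    names.append(n)
        series = {}
        for n in names:
            parts = [log.channel(n) for log in logs if n in log.channel_names]
            series[n] = (
                np.concatenate([p[0] for p in parts]),
                np.concatenate([p[1] for p in parts]),
            )
        return SignalLog(series)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per sample — timestamp_s, channel, value."""
        frames = [
            pd.DataFrame({"timestamp_s": t, "channel": name, "value": v})
            for name, (t, v) in self._series.items()
        ]
        if not frames:
            return pd.DataFrame(columns=["timestamp_s", "channel", "value"])
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignalLog":
        series = {}
        for name, grp in df.groupby("channel", sort=False):
            series[str(name)] = (
                grp["timestamp_s"].to_numpy(dtype=float),
                grp["value"].to_numpy(dtype=float),
            )
        return cls(series)


@dataclass
class WindowStats:
    """Raw pre-window statistics around one event (sigma may be 0)."""

    channels: ChannelSet
    mu: np.ndarray
    sigma: np.ndarray
    n_samples: np.ndarray


def window_means(
    log: SignalLog,
    channels: ChannelSet,
    t_event: float,
    pre_s: float,
    post_s: float,
    post_settle_s: float = 0.0,
) -> tuple[WindowStats, np.ndarray]:
    """Pre-window stats and post-window means around an event.

    Windows are half-open: pre = [t_event - pre_s, t_event), post =
    [t_event + post_settle_s, t_event + post_s); a sample exactly at the event
    timestamp belongs to the post window. ``post_settle_s`` optionally skips
    the first seconds of the post window so the mean measures the settled
    response rather than the rise. Each channel is windowed independently
    (channels may run at different sampling rates); fewer than 2 samples on
    either side raises :class:`WindowCoverageError`.
    """
    if not (pre_s > 0 and post_s > 0):
        raise ValueError("pre_s and post_s must be > 0")
    if not (0 <= post_settle_s < post_s):
        raise ValueError("post_settle_s must lie in [0, post_s)")
    pre_mu = np.empty(len(channels))
    pre_sd = np.empty(len(channels))
    pre_n = np.empty(len(channels), dtype=int)
    post_mu = np.empty(len(channels))
    for i, ch in enumerate(channels):
        t, v = log.channel(ch.name)
        dt = 1.0 / ch.sampling_rate
        if (t.size == 0 or t[0] > t_event - pre_s + 1.5 * dt
                or t[-1] < t_event + post_s - 1.5 * dt):
            raise WindowCoverageError(
                f"channel {ch.name!r}: log does not cover the window "
                f"[{t_event - pre_s:g}, {t_event + post_s:g}]s around t={t_event:g}s"
            )
        pre_mask = (t >= t_event - pre_s) & (t < t_event)
        post_mask = (t >= t_event + post_settle_s) & (t < t_event + post_s)
        n_pre, n_post = int(pre_mask.sum()), int(post_mask.sum())
        if n_pre < 2 or n_post < 2:
            raise WindowCoverageError(
                f"channel {ch.name!r}: window around t={t_event:g}s has "
                f"{n_pre} pre / {n_post} post samples (need >= 2 each)"
            )
        pre_vals = v[pre_mask]
        pre_mu[i] = pre_vals.mean()
        pre_sd[i] = pre_vals.std(ddof=1)
        pre_n[i] = n_pre
        post_mu[i] = v[post_mask].mean()
    return WindowStats(channels, pre_mu, pre_sd, pre_n), post_mu
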