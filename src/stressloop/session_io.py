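"""File formats, markers, configuration and evaluation reports.

All artifacts are plain delimited/structured text so sessions are diffable and
reproducible from files alone:

* SignalLog / MarkerLog / SessionLog — CSV with a ``# stressloop.<kind>.v1``
  schema header line; timestamps are seconds from session start.
* FeedbackModel — JSON at full float precision (shortest round-trip formatting,
  so matrices survive write/read bit-exactly).
* FittingProtocol / SessionConfig — YAML.

Marker logs synchronize the measurements with stimulus events: every applied
adjustment is written as an ``adjustment`` marker carrying the characteristic
and payload (level transition or continuous value, plus the resolved stimulus
id when catalog-backed).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .characteristics import Adjustment, CharacteristicSpec, StimulusCatalog, derive_scale
from .errors import ConfigError, LogIntegrityError, ReportError, SchemaError
from .rules import ContinuousRule, DiscreteRule, FeedbackModel
from .signal_model import Channel, ChannelSet, SignalLog

_SCHEMAS = {
    "signal": "# stressloop.signal.v1",
    "marker": "# stressloop.marker.v1",
    "session": "# stressloop.session.v1",
}

MARKER_KINDS = ("adjustment", "baseline_start", "baseline_end", "loop_start", "loop_end", "note")


@dataclass
class Marker:
    """One synchronization event."""

    timestamp_s: float
    kind: str
    characteristic: str = ""
    payload: str = ""
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in MARKER_KINDS:
            raise LogIntegrityError(f"unknown marker kind {self.kind!r}")


class MarkerLog(list):
    """Ordered list of markers (timestamps non-decreasing)."""

    def adjustments(self) -> list[Marker]:
        return [m for m in self if m.kind == "adjustment"]


def marker_from_adjustment(adj: Adjustment, t: float) -> Marker:
    return Marker(float(t), "adjustment", adj.characteristic, adj.payload_str(),
                  adj.stimulus_id or "")


def adjustment_from_marker(marker: Marker) -> Adjustment:
    """Reconstruct the adjustment payload carried by an adjustment marker."""
    if marker.kind != "adjustment":
        raise LogIntegrityError("only adjustment markers carry a payload")
    payload = marker.payload
    if ">" in payload:
        frm, to = payload.split(">", 1)
        return Adjustment(marker.characteristic, from_level=frm, to_level=to)
    try:
        x = float(payload)
    except ValueError:
        raise LogIntegrityError(f"malformed adjustment payload {payload!r}") from None
    return Adjustment(marker.characteristic, value=x, stimulus_id=marker.stimulus_id or None)


# -- CSV logs ----------------------------------------------------------------

def _write_csv(path, df: pd.DataFrame, schema: str) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(_SCHEMAS[schema] + "\n")
        df.to_csv(fh, index=False)


def _read_csv(path, schema: str) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if header != _SCHEMAS[schema]:
            raise SchemaError(f"{path}: expected header {_SCHEMAS[schema]!r}, found {header!r}")
        try:
            return pd.read_csv(fh)
        except Exception as exc:  # pandas reports the offending line number
            raise LogIntegrityError(f"{path}: malformed rows: {exc}") from exc


def write_signal_log(path, log: SignalLog) -> None:
    _write_csv(path, log.to_frame(), "signal")


def read_signal_log(path) -> SignalLog:
    df = _read_csv(path, "signal")
    required = {"timestamp_s", "channel", "value"}
    if set(df.columns) != required:
        raise LogIntegrityError(f"{path}: signal log columns must be {sorted(required)}")
    for col in ("timestamp_s", "value"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[~np.isfinite(df["timestamp_s"]) | ~np.isfinite(df["value"])]
    if len(bad):
        raise LogIntegrityError(f"{path}: non-numeric row at data line {bad[0] + 1}")
    return SignalLog.from_frame(df)


def write_marker_log(path, markers: MarkerLog) -> None:
    df = pd.DataFrame(
        [{"timestamp_s": m.timestamp_s, "kind": m.kind, "characteristic": m.characteristic,
          "payload": m.payload, "stimulus_id": m.stimulus_id} for m in markers],
        columns=["timestamp_s", "kind", "characteristic", "payload", "stimulus_id"])
    _write_csv(path, df, "marker")


def read_marker_log(path, known_characteristics: set[str] | None = None) -> MarkerLog:
    df = _read_csv(path, "marker").fillna("")
    out = MarkerLog()
    for i, row in df.iterrows():
        try:
            marker = Marker(float(row["timestamp_s"]), str(row["kind"]),
                            str(row["characteristic"]), str(row["payload"]),
                            str(row["stimulus_id"]))
        except (ValueError, LogIntegrityError) as exc:
            raise LogIntegrityError(f"{path}: data line {i + 1}: {exc}") from exc
        if (known_characteristics is not None and marker.kind == "adjustment"
                and marker.characteristic not in known_characteristics):
            raise LogIntegrityError(
                f"{path}: data line {i + 1}: unknown characteristic {marker.characteristic!r}")
        out.append(marker)
    return out


# -- catalogs ----------------------------------------------------------------

def write_catalog(path, catalog: StimulusCatalog) -> None:
    cols = ["stimulus_id", *catalog.dimensions]
    catalog.table[cols].to_csv(path, index=False)


def read_catalog(path, dimensions=None, inversions=None, bounds=(1.0, 9.0)) -> StimulusCatalog:
    df = pd.read_csv(path)
    dims = tuple(dimensions) if dimensions else tuple(c for c in df.columns if c != "stimulus_id")
    cat = StimulusCatalog(df, dims, dict(inversions or {}), tuple(bounds))
    return derive_scale(cat)


# -- feedback model ----------------------------------------------------------

def write_model(path, model: FeedbackModel) -> None:
    doc = {
        "schema": "stressloop.model.v1",
        "fitted_from": model.fitted_from,
        "channels": [{"name": c.name, "form": c.form, "direction": c.direction,
                      "sampling_rate": c.sampling_rate} for c in model.channels],
        "weights": model.weights.tolist(),
        "rules": {},
    }
    for name, rule in model.rules.items():
        if isinstance(rule, DiscreteRule):
            doc["rules"][name] = {"kind": "discrete",
                                  "transitions": [list(t) for t in rule.transitions],
                                  "D": rule.D.tolist(),
                                  "available": rule.available.astype(int).tolist()}
        else:
            doc["rules"][name] = {"kind": "continuous", "beta0": rule.beta0.tolist(),
                                  "beta1": rule.beta1.tolist(), "domain": list(rule.domain)}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_model(path) -> FeedbackModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "stressloop.model.v1":
        raise SchemaError(f"{path}: unexpected model schema {doc.get('schema')!r}")
    channels = ChannelSet([Channel(**c) for c in doc["channels"]])
    rules = {}
    for name, r in doc["rules"].items():
        if r["kind"] == "discrete":
            rules[name] = DiscreteRule(name, [tuple(t) for t in r["transitions"]],
                                       np.array(r["D"], dtype=float),
                                       np.array(r["available"], dtype=bool))
        else:
            rules[name] = ContinuousRule(name, np.array(r["beta0"]), np.array(r["beta1"]),
                                         tuple(r["domain"]))
    return FeedbackModel(channels, np.array(doc["weights"], dtype=float), rules,
                         doc.get("fitted_from", ""))


# -- protocol ----------------------------------------------------------------

def write_protocol(path, protocol) -> None:
    entries = []
    for adj, onset in protocol.sequence:
        e = {"onset_s": float(onset), "characteristic": adj.characteristic,
             "presentation": adj.presentation}
        if adj.duration_s is not None:
            e["duration_s"] = float(adj.duration_s)
        if adj.is_discrete:
            e["from_level"], e["to_level"] = adj.from_level, adj.to_level
        else:
            e["x"] = float(adj.value)
            if adj.stimulus_id:
                e["stimulus_id"] = adj.stimulus_id
        entries.append(e)
    doc = {"schema": "stressloop.protocol.v1",
           "pre_window_s": protocol.pre_window_s, "post_window_s": protocol.post_window_s,
           "post_settle_s": protocol.post_settle_s, "min_trials": protocol.min_trials,
           "sequence": entries}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_protocol(path):
    from .fitting import FittingProtocol  # lazy: avoids an import cycle

    doc = yaml.safe_load(Path(path).read_text())
    if doc.get("schema") != "stressloop.protocol.v1":
        raise SchemaError(f"{path}: unexpected protocol schema {doc.get('schema')!r}")
    sequence = []
    for e in doc["sequence"]:
        kw = {"presentation": e.get("presentation", "state_wise")}
        if "duration_s" in e:
            kw["duration_s"] = float(e["duration_s"])
        if "to_level" in e:
            adj = Adjustment(e["characteristic"], from_level=e["from_level"],
                             to_level=e["to_level"], **kw)
        else:
            adj = Adjustment(e["characteristic"], value=float(e["x"]),
                             stimulus_id=e.get("stimulus_id"), **kw)
        sequence.append((adj, float(e["onset_s"])))
    return FittingProtocol(sequence, pre_window_s=float(doc.get("pre_window_s", 10.0)),
                           post_window_s=float(doc.get("post_window_s", 10.0)),
                           post_settle_s=float(doc.get("post_settle_s", 0.0)),
                           min_trials=int(doc.get("min_trials", 1)))


# -- session log -------------------------------------------------------------

def write_session_log(path, session) -> None:
    _write_csv(path, session.frame, "session")


def read_session_log(path):
    from .controller import SessionLog  # lazy: avoids an import cycle

    return SessionLog(frame=_read_csv(path, "session"))


# -- configuration -----------------------------------------------------------

_CONFIG_KEYS = {
    "channels", "weights", "characteristics", "pre_window_s", "post_window_s",
    "post_settle_s", "baseline_duration_s", "loop_period_s", "state_window_s",
    "desired_state", "band", "seed", "subject_profile",
}


@dataclass
class SessionConfig:
    """Single configuration object driving a whole session.

    Validated eagerly: channel/characteristic invariants are checked at
    construction, and unknown keys in a config file are rejected.
    """

    channels: ChannelSet
    weights: np.ndarray
    characteristics: dict[str, CharacteristicSpec]
    pre_window_s: float = 10.0
    post_window_s: float = 10.0
    post_settle_s: float = 0.0
    baseline_duration_s: float = 60.0
    loop_period_s: float = 5.0
    state_window_s: float = 2.5
    desired_state: float | list = 1.0
    band: float = 0.5
    seed: int = 0
    subject_profile: str = "easy"

    def __post_init__(self) -> None:
        from .signal_model import validate_weights

        self.weights = validate_weights(self.weights)
        if self.weights.shape != (len(self.channels),):
            raise ConfigError("one weight per channel required")
        for v, label in ((self.pre_window_s, "pre_window_s"), (self.post_window_s, "post_window_s"),
                         (self.baseline_duration_s, "baseline_duration_s"),
                         (self.loop_period_s, "loop_period_s"), (self.state_window_s, "state_window_s")):
            if not v > 0:
                raise ConfigError(f"{label} must be > 0")
        if self.state_window_s > self.loop_period_s:
            raise ConfigError("state_window_s cannot exceed the loop period")


def read_config(path) -> SessionConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(doc) - _CONFIG_KEYS - {"schema"}
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    try:
        channels = ChannelSet([Channel(**c) for c in doc["channels"]])
        specs = {}
        for c in doc.get("characteristics", []):
            c = dict(c)
            name = c.pop("name")
            if "levels" in c:
                c["levels"] = tuple(c["levels"])
            if "scale_range" in c:
                c["scale_range"] = tuple(c["scale_range"])
            specs[name] = CharacteristicSpec(name=name, **c)
        weights = doc.get("weights", [1.0] * len(channels))
        scalars = {k: doc[k] for k in _CONFIG_KEYS
                   if k in doc and k not in ("channels", "weights", "characteristics")}
        return SessionConfig(channels=channels, weights=np.asarray(weights, dtype=float),
                             characteristics=specs, **scalars)
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_config(path, config: SessionConfig) -> None:
    doc = {
        "channels": [{"name": c.name, "form": c.form, "direction": c.direction,
                      "sampling_rate": c.sampling_rate} for c in config.channels],
        "weights": config.weights.tolist(),
        "characteristics": [],
        "pre_window_s": config.pre_window_s, "post_window_s": config.post_window_s,
        "post_settle_s": config.post_settle_s,
        "baseline_duration_s": config.baseline_duration_s,
        "loop_period_s": config.loop_period_s, "state_window_s": config.state_window_s,
        "desired_state": config.desired_state, "band": config.band,
        "seed": config.seed, "subject_profile": config.subject_profile,
    }
    for spec in config.characteristics.values():
        e = {"name": spec.name, "mode": spec.mode, "presentation": spec.presentation}
        if spec.mode == "discrete":
            e["levels"] = list(spec.levels)
            e["current_level"] = spec.current_level
        else:
            e["scale_range"] = list(spec.scale_range)
        if spec.transient_duration_s is not None:
            e["transient_duration_s"] = spec.transient_duration_s
        doc["characteristics"].append(e)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# -- evaluation --------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Tracking metrics recomputable from the session log they cite."""

    metrics: dict

    def to_json(self) -> str:
        return json.dumps(self.metrics, indent=1, sort_keys=True)


def evaluate(session, *, band: float = 0.5, uncontrolled=None) -> EvaluationReport:
    """Deterministic tracking metrics from a session log.

    Reports mean/median |s_d - s_c| overall and over the final third, time in a
    +/- ``band`` tolerance band around the target, and action counts. When a
    paired ``uncontrolled`` session is given, the ratio of final-third mean
    errors (controlled / uncontrolled) is included.
    """
    frame = session.frame
    if not len(frame):
        raise ReportError("empty session log")
    err = np.abs(frame["s_d"].to_numpy(dtype=float) - frame["s_c"].to_numpy(dtype=float))
    final = err[-max(1, len(err) // 3):]
    metrics = {
        "n_iterations": int(len(frame)),
        "mean_abs_error": float(err.mean()),
        "median_abs_error": float(np.median(err)),
        "final_third_mean_abs_error": float(final.mean()),
        "final_third_median_abs_error": float(np.median(final)),
        "time_in_band_pct": float(100.0 * np.mean(err <= band)),
        "band": float(band),
        "n_actions": int((frame["action"] != "none").sum()),
        "n_no_action": int((frame["action"] == "none").sum()),
        "complete": bool(frame["s_c"].notna().all()),
    }
    if uncontrolled is not None:
        other = evaluate(uncontrolled, band=band).metrics
        denom = other["final_third_mean_abs_error"]
        metrics["uncontrolled_final_third_mean_abs_error"] = denom
        metrics["final_third_error_ratio"] = (float(metrics["final_third_mean_abs_error"] / denom)
                                              if denom > 0 else float("nan"))
    return EvaluationReport(metrics)
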