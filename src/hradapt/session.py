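"""Game-session event model, user-model record and 1 Hz telemetry logs.

The adaptation component observes the game through six events
(``activityStarted``, ``activityFinished``, ``scoreObtained``,
``registerPostAnalytics``, ``executionMovement``, ``signalActivation``) and
folds them into a per-user record of played scenarios, final scores, play
counts and configuration history. Two of the events
(``registerPostAnalytics``, ``executionMovement``) are recorded for schema
completeness but drive no behaviour — the customisations they served were
pruned from the deployed component.

A :class:`SessionLog` is the 1 Hz telemetry of one participant-arm session:
per-tick raw/calibrated HR, the controller inputs (avgHR, w), the scenario's
serialized state and inputs, points and cumulative kilocalories, plus the
event list. Logs persist as a CSV and a JSON-lines event sidecar and
round-trip losslessly.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any

__all__ = [
    "EventKind",
    "GameEvent",
    "UserModelRecord",
    "SessionRow",
    "SessionLog",
    "EventSequenceError",
    "SessionLogError",
    "emit_event",
    "write_session_log",
    "read_session_log",
    "SESSION_CSV_HEADER",
]

SESSION_CSV_HEADER = [
    "t",
    "hr_raw",
    "hr_cal",
    "avg_hr",
    "w",
    "scenario",
    "state_json",
    "points",
    "kcal",
]


class EventKind(str, Enum):
    ACTIVITY_STARTED = "activityStarted"
    ACTIVITY_FINISHED = "activityFinished"
    SCORE_OBTAINED = "scoreObtained"
    REGISTER_POST_ANALYTICS = "registerPostAnalytics"
    EXECUTION_MOVEMENT = "executionMovement"
    SIGNAL_ACTIVATION = "signalActivation"


class EventSequenceError(ValueError):
    """An event arrived out of its required order."""


class SessionLogError(ValueError):
    """A persisted session log violates the dialect or an invariant."""


@dataclass(frozen=True)
class GameEvent:
    kind: EventKind
    t: float
    scenario: Any = None
    payload: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "t": self.t,
            "scenario": self.scenario,
            "payload": self.payload,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GameEvent":
        return cls(EventKind(d["kind"]), d["t"], d.get("scenario"), d.get("payload") or {})


@dataclass
class UserModelRecord:
    """User properties accumulated from the event stream.

    ``scoreRecord`` keeps the latest score per completed activity; scores
    after an activity that did not complete normally are discarded, so every
    stored score is trustworthy.
    """

    activities_history: list = field(default_factory=list)  # (scenario, start, end, completed)
    score_record: list = field(default_factory=list)  # (scenario, final score)
    scenario_counter: dict = field(default_factory=dict)
    conf_param_history: list = field(default_factory=list)  # (key, value, t)
    physiological_signals: Any = None  # reference to the session's HR/kcal stream
    _open_activity: tuple | None = field(default=None, repr=False)
    _last_finish_completed: bool | None = field(default=None, repr=False)


def emit_event(record: UserModelRecord, event: GameEvent) -> UserModelRecord:
    """Fold one event into the user-model record (mutates and returns it)."""
    k = event.kind
    if k is EventKind.ACTIVITY_STARTED:
        record._open_activity = (event.scenario, event.t)
        record._last_finish_completed = None
        record.scenario_counter[event.scenario] = record.scenario_counter.get(event.scenario, 0) + 1
    elif k is EventKind.ACTIVITY_FINISHED:
        if record._open_activity is None:
            raise EventSequenceError("activityFinished with no open activity")
        scenario, start = record._open_activity
        completed = bool(event.payload.get("completed", True))
        record.activities_history.append((scenario, start, event.t, completed))
        record._last_finish_completed = completed
        record._open_activity = None
    elif k is EventKind.SCORE_OBTAINED:
        if record._open_activity is None and record._last_finish_completed is None:
            raise EventSequenceError("scoreObtained with no matching activityStarted")
        if record._last_finish_completed is False:
            return record  # incomplete run: score untrusted, discarded
        record.score_record.append((event.scenario, event.payload.get("score")))
        record._last_finish_completed = None
    elif k in (EventKind.REGISTER_POST_ANALYTICS, EventKind.EXECUTION_MOVEMENT):
        pass  # recorded in the event list only; their customisations were pruned
    elif k is EventKind.SIGNAL_ACTIVATION:
        record.physiological_signals = event.payload.get("source", record.physiological_signals)
    return record


@dataclass(frozen=True)
class SessionRow:
    """One 1 Hz telemetry tick."""

    t: float
    hr_raw: float
    hr_cal: float
    avg_hr: float | None
    w: float | None
    scenario: Any
    state_json: str  # canonical JSON: {"state": ..., "inputs": ...}
    points: int
    kcal: float


@dataclass
class SessionLog:
    participant: str
    arm: str  # "UAS" | "CIS"
    rows: list = field(default_factory=list)
    events: list = field(default_factory=list)

    def validate(self) -> None:
        """Check row-level invariants; raises SessionLogError naming the row."""
        if self.arm not in ("UAS", "CIS"):
            raise SessionLogError(f"unknown arm {self.arm!r}")
        prev_t = -math.inf
        prev_kcal: dict = {}
        for i, r in enumerate(self.rows):
            if r.t <= prev_t:
                raise SessionLogError(f"row {i}: timestamp {r.t} not increasing")
            prev_t = r.t
            if r.scenario in prev_kcal and r.kcal < prev_kcal[r.scenario] - 1e-12:
                raise SessionLogError(
                    f"row {i}: kcal decreases within scenario {r.scenario} "
                    f"({prev_kcal[r.scenario]} -> {r.kcal})"
                )
            prev_kcal[r.scenario] = r.kcal


def _fmt(x: float | None) -> str:
    if x is None:
        return ""
    return repr(float(x))  # repr round-trips IEEE doubles exactly


def write_session_log(log: SessionLog, path: str | Path) -> Path:
    """Persist as ``<path>.csv`` + ``<path>.events.jsonl`` (lossless)."""
    log.validate()
    path = Path(path)
    csv_path = path if path.suffix == ".csv" else path.with_suffix(".csv")
    with csv_path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["# participant", log.participant, "arm", log.arm])
        writer.writerow(SESSION_CSV_HEADER)
        for r in log.rows:
            writer.writerow(
                [
                    _fmt(r.t),
                    _fmt(r.hr_raw),
                    _fmt(r.hr_cal),
                    _fmt(r.avg_hr),
                    _fmt(r.w),
                    r.scenario,
                    r.state_json,
                    r.points,
                    _fmt(r.kcal),
                ]
            )
    events_path = csv_path.with_suffix("").with_suffix(".events.jsonl")
    with events_path.open("w") as fh:
        for ev in log.events:
            fh.write(json.dumps(ev.to_dict(), sort_keys=True) + "\n")
    return csv_path


def _parse_scenario(raw: str) -> Any:
    try:
        return int(raw)
    except ValueError:
        return raw


def read_session_log(path: str | Path) -> SessionLog:
    """Read back a persisted session; validates all invariants on load."""
    csv_path = Path(path)
    if csv_path.suffix != ".csv":
        csv_path = csv_path.with_suffix(".csv")
    with csv_path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            meta = next(reader)
        except StopIteration:
            raise SessionLogError(f"{csv_path}: empty file")
        if len(meta) < 4 or meta[0] != "# participant":
            raise SessionLogError(f"{csv_path}: missing participant/arm preamble")
        participant, arm = meta[1], meta[3]
        header = next(reader, None)
        if header != SESSION_CSV_HEADER:
            missing = set(SESSION_CSV_HEADER) - set(header or [])
            raise SessionLogError(
                f"{csv_path}: bad header, missing column(s) {sorted(missing)}"
            )
        rows = []
        for rec in reader:
            rows.append(
                SessionRow(
                    t=float(rec[0]),
                    hr_raw=float(rec[1]),
                    hr_cal=float(rec[2]),
                    avg_hr=float(rec[3]) if rec[3] else None,
                    w=float(rec[4]) if rec[4] else None,
                    scenario=_parse_scenario(rec[5]),
                    state_json=rec[6],
                    points=int(rec[7]),
                    kcal=float(rec[8]),
                )
            )
    events_path = csv_path.with_suffix("").with_suffix(".events.jsonl")
    events = []
    if events_path.exists():
        with events_path.open() as fh:
            for line in fh:
                line = line.strip()
                if line:
                    events.append(GameEvent.from_dict(json.loads(line)))
    log = SessionLog(participant, arm, rows, events)
    log.validate()
    return log
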