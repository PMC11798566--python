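"""Typed data model for raw remote-monitoring event streams, with readers and writers.

The streams mirror what a passive-sensing mHealth deployment collects from a
participant's smartphone and wearable: phone lock-state transitions, app usage
events (including the OTHER events that mark incoming notifications), ambient
light samples, minute-level step counts, wearable-detected sleep intervals, and
the notification/start/finish timestamps of remotely pushed questionnaires.

On disk each stream kind is a comma-separated file with a header row, or an
equivalent JSON-lines dialect (one object per line, same field names).
Timestamps are seconds since the Unix epoch, UTC; calendar-day assignment is
done downstream with an explicit per-cohort UTC offset.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence


class StreamFormatError(ValueError):
    """Raised when a stream file violates its schema.

    Carries the offending line number and field name so that bad rows in large
    exports can be located.
    """

    def __init__(self, message: str, *, line: int | None = None, field: str | None = None):
        loc = []
        if line is not None:
            loc.append(f"line {line}")
        if field is not None:
            loc.append(f"field '{field}'")
        super().__init__(f"{message} ({', '.join(loc)})" if loc else message)
        self.line = line
        self.field = field


class PhoneState(enum.Enum):
    STANDBY = "STANDBY"
    UNLOCKED = "UNLOCKED"
    SHUTDOWN = "SHUTDOWN"
    BOOTED = "BOOTED"


class AppCategory(enum.Enum):
    SOCIAL = "SOCIAL"
    COMMUNICATION = "COMMUNICATION"
    OTHER_CATEGORY = "OTHER_CATEGORY"


class AppEventType(enum.Enum):
    """Android usage-event classes.

    OTHER events are emitted when a notification is posted; FOREGROUND or
    INTERACTION events follow if the user engages with the app; BACKGROUND
    events happen without user involvement.
    """

    OTHER = "OTHER"
    FOREGROUND = "FOREGROUND"
    INTERACTION = "INTERACTION"
    BACKGROUND = "BACKGROUND"


class Group(enum.Enum):
    ADHD = "ADHD"
    COMPARISON = "COMPARISON"


def _check_time(value: float, name: str) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and non-negative, got {value!r}")


@dataclass(frozen=True, slots=True)
class PhoneStatusEvent:
    participant_id: str
    timestamp: float
    state: PhoneState

    def __post_init__(self):
        _check_time(self.timestamp, "timestamp")


@dataclass(frozen=True, slots=True)
class AppEvent:
    participant_id: str
    timestamp: float
    package: str
    category: AppCategory
    event_type: AppEventType

    def __post_init__(self):
        _check_time(self.timestamp, "timestamp")


@dataclass(frozen=True, slots=True)
class LightReading:
    participant_id: str
    timestamp: float
    illuminance: float  # lux

    def __post_init__(self):
        _check_time(self.timestamp, "timestamp")
        if not math.isfinite(self.illuminance) or self.illuminance < 0:
            raise ValueError(f"illuminance must be >= 0, got {self.illuminance!r}")


@dataclass(frozen=True, slots=True)
class StepRecord:
    participant_id: str
    timestamp: float  # start of the recording minute
    steps: int

    def __post_init__(self):
        _check_time(self.timestamp, "timestamp")
        if self.steps < 0 or int(self.steps) != self.steps:
            raise ValueError(f"steps must be a non-negative integer, got {self.steps!r}")


@dataclass(frozen=True, slots=True)
class SleepInterval:
    participant_id: str
    start: float
    end: float

    def __post_init__(self):
        _check_time(self.start, "start")
        _check_time(self.end, "end")
        if not self.start < self.end:
            raise ValueError(f"sleep interval requires start < end, got [{self.start}, {self.end})")


@dataclass(frozen=True, slots=True)
class QuestionnaireRecord:
    """Timestamps of one remotely pushed questionnaire.

    ``started_at``/``finished_at`` are None when the participant never opened
    or never completed the questionnaire within its availability window.
    """

    participant_id: str
    wave: int
    questionnaire_name: str
    notified_at: float
    started_at: float | None = None
    finished_at: float | None = None

    def __post_init__(self):
        _check_time(self.notified_at, "notified_at")
        if self.started_at is not None and self.started_at < self.notified_at:
            raise ValueError("started_at precedes notified_at")
        if self.finished_at is not None:
            if self.started_at is None:
                raise ValueError("finished_at present without started_at")
            if self.finished_at < self.started_at:
                raise ValueError("finished_at precedes started_at")
        if self.wave < 1:
            raise ValueError(f"wave must be a positive index, got {self.wave}")


@dataclass(frozen=True, slots=True)
class ManifestEntry:
    participant_id: str
    group: Group
    enrollment_date: str  # ISO calendar date


class StreamKind(enum.Enum):
    PHONE_STATUS = "phone_status"
    APP_EVENT = "app_event"
    LIGHT = "light"
    STEPS = "steps"
    SLEEP = "sleep"
    QUESTIONNAIRE = "questionnaire"


def _opt_float(s):
    return None if s in ("", None) else float(s)


# kind -> (record class, [(field, parse, serialize)], sort-time attribute)
_SCHEMAS = {
    StreamKind.PHONE_STATUS: (
        PhoneStatusEvent,
        [("participant_id", str, str), ("timestamp", float, repr), ("state", PhoneState, lambda v: v.value)],
        "timestamp",
    ),
    StreamKind.APP_EVENT: (
        AppEvent,
        [
            ("participant_id", str, str),
            ("timestamp", float, repr),
            ("package", str, str),
            ("category", AppCategory, lambda v: v.value),
            ("event_type", AppEventType, lambda v: v.value),
        ],
        "timestamp",
    ),
    StreamKind.LIGHT: (
        LightReading,
        [("participant_id", str, str), ("timestamp", float, repr), ("illuminance", float, repr)],
        "timestamp",
    ),
    StreamKind.STEPS: (
        StepRecord,
        [("participant_id", str, str), ("timestamp", float, repr), ("steps", int, str)],
        "timestamp",
    ),
    StreamKind.SLEEP: (
        SleepInterval,
        [("participant_id", str, str), ("start", float, repr), ("end", float, repr)],
        "start",
    ),
    StreamKind.QUESTIONNAIRE: (
        QuestionnaireRecord,
        [
            ("participant_id", str, str),
            ("wave", int, str),
            ("questionnaire_name", str, str),
            ("notified_at", float, repr),
            ("started_at", _opt_float, lambda v: "" if v is None else repr(v)),
            ("finished_at", _opt_float, lambda v: "" if v is None else repr(v)),
        ],
        "notified_at",
    ),
}

KIND_FOR_TYPE = {cls: kind for kind, (cls, _, _) in _SCHEMAS.items()}


def sort_key(kind: StreamKind):
    time_attr = _SCHEMAS[kind][2]
    return lambda rec: (rec.participant_id, getattr(rec, time_attr))


def _parse_row(kind: StreamKind, values: dict, line: int):
    cls, schema, _ = _SCHEMAS[kind]
    kwargs = {}
    for name, parse, _ser in schema:
        raw = values.get(name)
        if raw is None:
            raise StreamFormatError("missing value", line=line, field=name)
        try:
            if isinstance(parse, type) and issubclass(parse, enum.Enum):
                kwargs[name] = parse(raw)
            else:
                kwargs[name] = parse(raw)
        except (ValueError, KeyError) as exc:
            raise StreamFormatError(f"cannot parse {raw!r}: {exc}", line=line, field=name) from None
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise StreamFormatError(str(exc), line=line) from None


def _check_sleep_overlap(records: Sequence[SleepInterval]) -> None:
    prev_end: dict[str, float] = {}
    for rec in records:
        if rec.participant_id in prev_end and rec.start < prev_end[rec.participant_id]:
            raise StreamFormatError(
                f"overlapping sleep intervals for participant {rec.participant_id!r} at {rec.start}"
            )
        prev_end[rec.participant_id] = max(prev_end.get(rec.participant_id, 0.0), rec.end)


def read_stream(path: str | Path, kind: StreamKind) -> list:
    """Read, validate and sort one event stream.

    CSV (``.csv``) and JSON-lines (``.jsonl``/``.ndjson``) are detected by
    extension. Records are returned sorted by (participant_id, time); the order
    on disk is irrelevant. An empty file (header only, or no lines) yields an
    empty list. Malformed rows raise :class:`StreamFormatError` naming the line
    and field.
    """
    path = Path(path)
    cls, schema, _ = _SCHEMAS[kind]
    names = [name for name, _, _ in schema]
    records = []
    if path.suffix in (".jsonl", ".ndjson"):
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise StreamFormatError(f"invalid JSON: {exc}", line=line_no) from None
                records.append(_parse_row(kind, {k: ("" if v is None else v) for k, v in obj.items()}, line_no))
    else:
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                return []
            if header != names:
                raise StreamFormatError(
                    f"header {header!r} does not match {kind.value} schema {names!r}", line=1
                )
            for line_no, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != len(names):
                    raise StreamFormatError(f"expected {len(names)} fields, got {len(row)}", line=line_no)
                records.append(_parse_row(kind, dict(zip(names, row)), line_no))
    records.sort(key=sort_key(kind))
    if kind is StreamKind.SLEEP:
        _check_sleep_overlap(records)
    return records


def write_stream(records: Iterable, path: str | Path, kind: StreamKind | None = None) -> Path:
    """Write a homogeneous sequence of events; CSV or JSON-lines by extension.

    Round-trip contract: ``read_stream(write_stream(x)) == sorted(x)``.
    """
    records = list(records)
    path = Path(path)
    if kind is None:
        if not records:
            raise ValueError("cannot infer stream kind from an empty sequence; pass kind=")
        kind = KIND_FOR_TYPE[type(records[0])]
    cls, schema, _ = _SCHEMAS[kind]
    for rec in records:
        if type(rec) is not cls:
            raise ValueError(f"heterogeneous stream: expected {cls.__name__}, got {type(rec).__name__}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".jsonl", ".ndjson"):
        with open(path, "w") as fh:
            for rec in records:
                obj = {}
                for name, _p, ser in schema:
                    val = getattr(rec, name)
                    obj[name] = None if val is None else (val.value if isinstance(val, enum.Enum) else val)
                fh.write(json.dumps(obj) + "\n")
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([name for name, _, _ in schema])
            for rec in records:
                writer.writerow([ser(getattr(rec, name)) for name, _p, ser in schema])
    return path


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read the cohort manifest (participant_id, group, enrollment_date)."""
    entries = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for line_no, row in enumerate(reader, start=2):
            pid = row.get("participant_id")
            if pid is None or row.get("group") is None:
                raise StreamFormatError("manifest requires participant_id and group", line=line_no)
            if pid in seen:
                raise StreamFormatError(f"duplicate participant id {pid!r}", line=line_no, field="participant_id")
            seen.add(pid)
            try:
                group = Group(row["group"])
            except ValueError:
                raise StreamFormatError(f"unknown group {row['group']!r}", line=line_no, field="group") from None
            entries.append(ManifestEntry(pid, group, row.get("enrollment_date", "")))
    return entries


def write_manifest(entries: Sequence[ManifestEntry], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "group", "enrollment_date"])
        for e in entries:
            writer.writerow([e.participant_id, e.group.value, e.enrollment_date])
    return path


def read_category_map(path: str | Path) -> dict[str, AppCategory]:
    """Read the static package -> app-store-category map (two-column CSV)."""
    mapping = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["package", "category"]:
            raise StreamFormatError("category map header must be 'package,category'", line=1)
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                mapping[row[0]] = AppCategory(row[1])
            except (IndexError, ValueError):
                raise StreamFormatError(f"bad category row {row!r}", line=line_no, field="category") from None
    return mapping


def write_category_map(mapping: dict[str, AppCategory], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["package", "category"])
        for package, category in sorted(mapping.items()):
            writer.writerow([package, category.value])
    return path
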