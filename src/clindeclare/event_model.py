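"""In-memory model of clinical event logs.

Events carry arbitrarily many typed attributes, each classified into one of
seven clinically meaningful kinds (time, demography, observation, evaluation,
instruction, action, admin).  The last five mirror the openEHR entry
categories; *time* holds lifecycle timestamps and *demography* patient
identity data.  The classification is what lets data conditions between two
activities be arranged in a 7x7 constrained-relationship matrix, with the
row/column index of a condition naming the attribute kind it constrains.

Attribute values use the five XES value types: boolean, integer, float,
string and datetime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import IntEnum
from typing import Iterable, Mapping, Sequence, Union

from .errors import ClinDeclareWarning, LogInputError, StructuralError

__all__ = [
    "AttributeKind",
    "AttributeValue",
    "ClinicalAttribute",
    "Event",
    "Trace",
    "EventLog",
    "build_log",
    "canonical_time",
    "parse_timestamp",
    "log_to_rows",
    "read_csv_log",
    "write_csv_log",
]

AttributeValue = Union[bool, int, float, str, datetime]

#: reserved attribute names resolving to the lifecycle timestamps of an event
START_TIME = "start time"
COMPLETE_TIME = "complete time"


class AttributeKind(IntEnum):
    """The seven attribute kinds; indices are stable and used as matrix axes.

    1=time, 2=demography, 3=observation, 4=evaluation, 5=instruction,
    6=action, 7=admin.
    """

    TIME = 1
    DEMOGRAPHY = 2
    OBSERVATION = 3
    EVALUATION = 4
    INSTRUCTION = 5
    ACTION = 6
    ADMIN = 7

    @classmethod
    def from_name(cls, name: str) -> "AttributeKind":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown attribute kind: {name!r}") from None

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class ClinicalAttribute:
    """A named, kind-classified attribute value attached to one event."""

    name: str
    kind: AttributeKind
    value: AttributeValue

    def __post_init__(self) -> None:
        if not self.name:
            raise StructuralError("attribute name must be non-empty")
        if self.kind == AttributeKind.TIME and not isinstance(self.value, datetime):
            raise StructuralError(
                f"time attribute {self.name!r} must hold a datetime, got {type(self.value).__name__}"
            )


@dataclass
class Event:
    """One occurrence of a clinical activity.

    ``start_time`` / ``complete_time`` are the reserved lifecycle time
    attributes; at least one must be present.  All other attributes live in
    ``attributes`` keyed by (unique) name.
    """

    event_id: str
    activity: str
    start_time: datetime | None = None
    complete_time: datetime | None = None
    attributes: dict[str, ClinicalAttribute] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.activity:
            raise StructuralError(f"event {self.event_id!r} has an empty activity name")
        if self.start_time is None and self.complete_time is None:
            raise StructuralError(f"event {self.event_id!r} has neither start nor complete time")
        if (
            self.start_time is not None
            and self.complete_time is not None
            and self.start_time > self.complete_time
        ):
            raise StructuralError(
                f"event {self.event_id!r}: start time {self.start_time} after complete time {self.complete_time}"
            )

    def get(self, name: str) -> AttributeValue | None:
        """Resolve an attribute by name, including the reserved time names."""
        if name == COMPLETE_TIME:
            return self.complete_time
        if name == START_TIME:
            return self.start_time
        attr = self.attributes.get(name)
        return None if attr is None else attr.value

    def with_attribute(self, attr: ClinicalAttribute) -> "Event":
        attrs = dict(self.attributes)
        attrs[attr.name] = attr
        return replace(self, attributes=attrs)


def canonical_time(e: Event) -> datetime:
    """The ordering timestamp of an event: complete time if present, else start time."""
    if e.complete_time is not None:
        return e.complete_time
    if e.start_time is not None:
        return e.start_time
    raise StructuralError(f"event {e.event_id!r} has no time attribute")


@dataclass
class Trace:
    """The ordered event sequence of one case (patient episode).

    Events are sorted stably by canonical time on construction, so ties keep
    their input order.
    """

    case_id: str
    events: list[Event] = field(default_factory=list)
    attributes: dict[str, AttributeValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.case_id:
            raise StructuralError("trace has an empty case id")
        self.events = sorted(self.events, key=canonical_time)

    def activities(self) -> list[str]:
        return [e.activity for e in self.events]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass
class EventLog:
    """A set of traces; the alphabet is the union of activities over all events."""

    traces: list[Trace] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.traces:
            if t.case_id in seen:
                raise StructuralError(f"duplicate case id {t.case_id!r} in log")
            seen.add(t.case_id)

    @property
    def alphabet(self) -> set[str]:
        return {e.activity for t in self.traces for e in t.events}

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)


# --------------------------------------------------------------------------
# timestamp parsing

_TS_FORMATS = ("%Y/%m/%d %H:%M", "%Y/%m/%d %H:%M:%S")


def parse_timestamp(value: str | datetime) -> datetime:
    """Parse ISO-8601 or the tabular dialect ``2019/1/13 10:16``.

    All times are naive local times; a timezone offset, if present, is
    dropped after normalisation to the stated local clock time.
    """
    if isinstance(value, datetime):
        return value.replace(tzinfo=None) if value.tzinfo else value
    text = str(value).strip()
    try:
        dt = datetime.fromisoformat(text)
        return dt.replace(tzinfo=None) if dt.tzinfo else dt
    except ValueError:
        pass
    for fmt in _TS_FORMATS:
        try:
            return datetime.strptime(text, fmt)
        except ValueError:
            continue
    raise LogInputError(f"unparseable timestamp: {text!r}")


def _coerce_extra(text: str) -> AttributeValue:
    """Best-effort typing for extra tabular columns: int, then float, else string."""
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        pass
    return text


def _kind_for(
    name: str, dictionary: Mapping[str, AttributeKind] | None, warned: set[str]
) -> AttributeKind:
    if name in (START_TIME, COMPLETE_TIME):
        return AttributeKind.TIME
    if dictionary and name in dictionary:
        return dictionary[name]
    if name not in warned:
        warned.add(name)
        warnings.warn(
            f"attribute {name!r} missing from the attribute dictionary; defaulting to kind=admin",
            ClinDeclareWarning,
            stacklevel=3,
        )
    return AttributeKind.ADMIN


# --------------------------------------------------------------------------
# tabular construction

_RESERVED_COLUMNS = {"Case_ID", "Event_ID", "Activity", "Actor", "Timestamp", "Start_Timestamp"}


def build_log(
    rows: Iterable[Mapping[str, object]],
    attribute_dictionary: Mapping[str, AttributeKind] | None = None,
    actor_attribute: str = "executor",
) -> EventLog:
    """Build an :class:`EventLog` from tabular records.

    Each record needs ``Case_ID``, ``Activity`` and ``Timestamp``;
    ``Event_ID``, ``Actor``, ``Start_Timestamp`` and arbitrary extra columns
    are optional.  The single ``Timestamp`` column is taken as the complete
    time; ``Start_Timestamp``, when given, becomes the start time.  The actor
    is stored as an attribute of kind=action (named ``executor`` by default).
    Extra columns are typed by the attribute dictionary; unmapped names
    default to kind=admin with a warning.
    """
    warned: set[str] = set()
    cases: dict[str, list[Event]] = {}
    counter = 0
    for n, row in enumerate(rows, start=1):
        case_id = str(row.get("Case_ID") or "").strip()
        activity = str(row.get("Activity") or "").strip()
        if not case_id:
            raise LogInputError(f"row {n}: missing Case_ID")
        if not activity:
            raise LogInputError(f"row {n}: missing Activity")
        ts_raw = row.get("Timestamp")
        if ts_raw is None or (isinstance(ts_raw, str) and not ts_raw.strip()):
            raise LogInputError(f"row {n}: missing Timestamp")
        try:
            complete = parse_timestamp(ts_raw)  # type: ignore[arg-type]
        except LogInputError as exc:
            raise LogInputError(f"row {n}: {exc}") from None
        start = None
        start_raw = row.get("Start_Timestamp")
        if start_raw is not None and str(start_raw).strip():
            try:
                start = parse_timestamp(start_raw)  # type: ignore[arg-type]
            except LogInputError as exc:
                raise LogInputError(f"row {n}: {exc}") from None
        counter += 1
        event_id = str(row.get("Event_ID") or counter)
        attrs: dict[str, ClinicalAttribute] = {}
        actor = row.get("Actor")
        if actor is not None and str(actor).strip():
            attrs[actor_attribute] = ClinicalAttribute(
                actor_attribute, AttributeKind.ACTION, str(actor).strip()
            )
        for key, raw in row.items():
            if key in _RESERVED_COLUMNS or raw is None:
                continue
            text = str(raw).strip() if isinstance(raw, str) else raw
            if text == "" or text is None:
                continue
            value: AttributeValue = _coerce_extra(text) if isinstance(text, str) else text  # type: ignore[assignment]
            kind = _kind_for(key, attribute_dictionary, warned)
            if kind == AttributeKind.TIME and not isinstance(value, datetime):
                value = parse_timestamp(str(raw))
            attrs[key] = ClinicalAttribute(key, kind, value)
        cases.setdefault(case_id, []).append(
            Event(event_id, activity, start_time=start, complete_time=complete, attributes=attrs)
        )
    return EventLog([Trace(cid, evs) for cid, evs in cases.items()])


def log_to_rows(log: EventLog, actor_attribute: str = "executor") -> list[dict[str, object]]:
    """Flatten a log back to tabular records (inverse of :func:`build_log`)."""
    rows: list[dict[str, object]] = []
    for trace in log:
        for e in trace:
            row: dict[str, object] = {
                "Case_ID": trace.case_id,
                "Event_ID": e.event_id,
                "Activity": e.activity,
            }
            actor = e.attributes.get(actor_attribute)
            if actor is not None:
                row["Actor"] = actor.value
            if e.complete_time is not None:
                row["Timestamp"] = e.complete_time.isoformat(sep=" ")
            if e.start_time is not None:
                row["Start_Timestamp"] = e.start_time.isoformat(sep=" ")
            for name, attr in e.attributes.items():
                if name == actor_attribute:
                    continue
                row[name] = attr.value
            rows.append(row)
    return rows


def read_csv_log(
    path,
    attribute_dictionary: Mapping[str, AttributeKind] | None = None,
    actor_attribute: str = "executor",
) -> EventLog:
    """Read the flat CSV dialect (header ``Case_ID,Event_ID,Activity,Actor,Timestamp[,...]``)."""
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
    return build_log(rows, attribute_dictionary, actor_attribute)


def write_csv_log(log: EventLog, path, actor_attribute: str = "executor") -> None:
    """Write a log in the flat CSV dialect (one row per event, Timestamp = complete time)."""
    import csv

    rows = log_to_rows(log, actor_attribute)
    columns = ["Case_ID", "Event_ID", "Activity", "Actor", "Timestamp", "Start_Timestamp"]
    extra = sorted({k for r in rows for k in r} - set(columns))
    columns = [c for c in columns if any(c in r for r in rows)] + extra
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: _csv_cell(v) for k, v in row.items()})


def _csv_cell(value: object) -> object:
    if isinstance(value, datetime):
        return value.isoformat(sep=" ")
    return value
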