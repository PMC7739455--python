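"""Read and write event logs as XES (IEEE 1849) documents.

The writer emits the subset of XES the event model uses: string, date, int,
float and boolean attribute elements, ``concept:name`` for activities and
case ids, ``time:timestamp`` for timestamps, ``lifecycle:transition`` for
start/complete and ``identity:id`` for event ids.  The attribute-kind
classification survives round-trips as a nested ``clin:kind`` string
attribute.

An in-memory event holding both a start and a complete time is written as
two adjacent XES events (lifecycle ``start`` then ``complete``); the reader
merges exactly that adjacent pattern back into one event.  Non-adjacent
lifecycle pairs are kept as separate events — the instance correlation
needed for global matching is not part of the log format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime
from typing import Mapping

from lxml import etree

from .errors import ClinDeclareWarning, XesParseError
from .event_model import (
    AttributeKind,
    AttributeValue,
    ClinicalAttribute,
    Event,
    EventLog,
    Trace,
    parse_timestamp,
)

__all__ = ["XesMappingConfig", "read_xes", "write_xes"]

KIND_KEY = "clin:kind"


@dataclass(frozen=True)
class XesMappingConfig:
    """Which XES attribute keys carry the standard event fields."""

    activity_key: str = "concept:name"
    timestamp_key: str = "time:timestamp"
    lifecycle_key: str = "lifecycle:transition"
    resource_key: str = "org:resource"
    identity_key: str = "identity:id"
    resource_attribute: str = "executor"
    attribute_dictionary: Mapping[str, AttributeKind] = field(default_factory=dict)

    def __post_init__(self):
        for key in (self.activity_key, self.timestamp_key, self.lifecycle_key, self.resource_key):
            if not key:
                raise ValueError("XES mapping keys must be non-empty")


_TYPE_TAGS = {bool: "boolean", int: "int", float: "float", str: "string", datetime: "date"}


def _value_to_text(value: AttributeValue) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, datetime):
        return value.isoformat()
    return str(value)


def _text_to_value(tag: str, text: str) -> AttributeValue:
    if tag == "boolean":
        return text.strip().lower() == "true"
    if tag == "int":
        return int(text)
    if tag == "float":
        return float(text)
    if tag == "date":
        return parse_timestamp(text)
    return text


def _localname(el) -> str:
    return etree.QName(el).localname


# --------------------------------------------------------------------------
# writing


def _attr_element(parent, tag: str, key: str, value: AttributeValue):
    el = etree.SubElement(parent, tag)
    el.set("key", key)
    el.set("value", _value_to_text(value))
    return el


def _write_clinical_attr(parent, attr: ClinicalAttribute) -> None:
    tag = _TYPE_TAGS[type(attr.value)] if type(attr.value) in _TYPE_TAGS else None
    if tag is None:
        for base, t in _TYPE_TAGS.items():
            if isinstance(attr.value, base):
                tag = t
                break
    el = _attr_element(parent, tag or "string", attr.name, attr.value)
    _attr_element(el, "string", KIND_KEY, attr.kind.label)


def write_xes(log: EventLog, path, cfg: XesMappingConfig | None = None) -> None:
    """Serialize a log to an XES file; ``read_xes`` inverts it on all modeled fields."""
    cfg = cfg or XesMappingConfig()
    root = etree.Element("log")
    root.set("xes.version", "1.0")
    root.set("xes.features", "nested-attributes")
    for trace in log:
        tr = etree.SubElement(root, "trace")
        _attr_element(tr, "string", cfg.activity_key, trace.case_id)
        for name, value in trace.attributes.items():
            tag = next((t for base, t in _TYPE_TAGS.items() if isinstance(value, base)), "string")
            _attr_element(tr, tag, name, value)
        for e in trace:
            if e.start_time is not None and e.complete_time is not None:
                first = etree.SubElement(tr, "event")
                _attr_element(first, "string", cfg.activity_key, e.activity)
                _attr_element(first, "string", cfg.lifecycle_key, "start")
                _attr_element(first, "date", cfg.timestamp_key, e.start_time)
                _attr_element(first, "string", cfg.identity_key, e.event_id)
                second = etree.SubElement(tr, "event")
                _write_event_body(second, e, cfg, lifecycle="complete", ts=e.complete_time)
            elif e.complete_time is not None:
                el = etree.SubElement(tr, "event")
                _write_event_body(el, e, cfg, lifecycle="complete", ts=e.complete_time)
            else:
                el = etree.SubElement(tr, "event")
                _write_event_body(el, e, cfg, lifecycle="start", ts=e.start_time)
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _write_event_body(el, e: Event, cfg: XesMappingConfig, lifecycle: str, ts) -> None:
    _attr_element(el, "string", cfg.activity_key, e.activity)
    _attr_element(el, "string", cfg.lifecycle_key, lifecycle)
    _attr_element(el, "date", cfg.timestamp_key, ts)
    _attr_element(el, "string", cfg.identity_key, e.event_id)
    for attr in e.attributes.values():
        _write_clinical_attr(el, attr)


# --------------------------------------------------------------------------
# reading

_ATTR_TAGS = {"string", "date", "int", "float", "boolean"}


@dataclass
class _RawEvent:
    activity: str
    lifecycle: str
    timestamp: datetime | None
    event_id: str | None
    attributes: dict[str, ClinicalAttribute]


def read_xes(path, cfg: XesMappingConfig | None = None) -> EventLog:
    """Parse an XES file into an :class:`EventLog`.

    Adjacent (activity, start) + (activity, complete) XES event pairs merge
    into one event carrying both times; any other lifecycle value maps to
    the complete time (a lone ``start`` keeps only a start time).  Traces
    lacking a case-id attribute get a positional id with a warning.
    """
    cfg = cfg or XesMappingConfig()
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise XesParseError(f"{path}: {exc}") from None
    root = tree.getroot()
    if _localname(root) != "log":
        raise XesParseError(f"{path}: root element is <{_localname(root)}>, expected <log>")
    traces: list[Trace] = []
    for pos, tr in enumerate((el for el in root if _localname(el) == "trace"), start=1):
        case_id = None
        trace_attrs: dict[str, AttributeValue] = {}
        raw_events: list[_RawEvent] = []
        for el in tr:
            name = _localname(el)
            if name == "event":
                raw_events.append(_read_event(el, cfg, path))
            elif name in _ATTR_TAGS:
                key = el.get("key", "")
                if key == cfg.activity_key:
                    case_id = el.get("value", "")
                else:
                    trace_attrs[key] = _text_to_value(name, el.get("value", ""))
        if not case_id:
            case_id = f"trace-{pos}"
            warnings.warn(
                f"trace #{pos} has no {cfg.activity_key} attribute; using positional id",
                ClinDeclareWarning,
                stacklevel=2,
            )
        traces.append(Trace(case_id, _merge_lifecycle(raw_events), trace_attrs))
    return EventLog(traces)


def _read_event(el, cfg: XesMappingConfig, path) -> _RawEvent:
    activity = ""
    lifecycle = "complete"
    timestamp = None
    event_id = None
    attributes: dict[str, ClinicalAttribute] = {}
    for child in el:
        tag = _localname(child)
        if tag not in _ATTR_TAGS:
            continue
        key = child.get("key", "")
        raw = child.get("value", "")
        if key == cfg.activity_key:
            activity = raw
        elif key == cfg.lifecycle_key:
            lifecycle = raw.strip().lower()
        elif key == cfg.timestamp_key:
            timestamp = parse_timestamp(raw)
        elif key == cfg.identity_key:
            event_id = raw
        else:
            kind = _nested_kind(child)
            if kind is None:
                if key == cfg.resource_key:
                    key, kind = cfg.resource_attribute, AttributeKind.ACTION
                else:
                    kind = cfg.attribute_dictionary.get(key, AttributeKind.ADMIN)
            attributes[key] = ClinicalAttribute(key, kind, _text_to_value(tag, raw))
    if not activity:
        raise XesParseError(f"{path}: event without {cfg.activity_key}")
    if timestamp is None:
        raise XesParseError(f"{path}: event {activity!r} without {cfg.timestamp_key}")
    return _RawEvent(activity, lifecycle, timestamp, event_id, attributes)


def _nested_kind(el) -> AttributeKind | None:
    for child in el:
        try:
            if _localname(child) == "string" and child.get("key") == KIND_KEY:
                return AttributeKind.from_name(child.get("value", ""))
        except ValueError:
            return None
    return None


def _merge_lifecycle(raw_events: list[_RawEvent]) -> list[Event]:
    events: list[Event] = []
    counter = 0
    k = 0
    while k < len(raw_events):
        cur = raw_events[k]
        nxt = raw_events[k + 1] if k + 1 < len(raw_events) else None
        counter += 1
        if (
            cur.lifecycle == "start"
            and nxt is not None
            and nxt.activity == cur.activity
            and nxt.lifecycle == "complete"
            # split lifecycle halves of one event share their identity:id;
            # distinct ids mean distinct events and block the merge
            and (cur.event_id is None or nxt.event_id is None or cur.event_id == nxt.event_id)
        ):
            attrs = dict(cur.attributes)
            attrs.update(nxt.attributes)
            events.append(
                Event(
                    nxt.event_id or cur.event_id or str(counter),
                    cur.activity,
                    start_time=cur.timestamp,
                    complete_time=nxt.timestamp,
                    attributes=attrs,
                )
            )
            k += 2
        elif cur.lifecycle == "start":
            events.append(
                Event(
                    cur.event_id or str(counter),
                    cur.activity,
                    start_time=cur.timestamp,
                    attributes=cur.attributes,
                )
            )
            k += 1
        else:
            events.append(
                Event(
                    cur.event_id or str(counter),
                    cur.activity,
                    complete_time=cur.timestamp,
                    attributes=cur.attributes,
                )
            )
            k += 1
    return events
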