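"""Shared fixtures and hypothesis strategies."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest
from hypothesis import HealthCheck, settings, strategies as st

from clindeclare.event_model import (
    AttributeKind,
    ClinicalAttribute,
    Event,
    EventLog,
    Trace,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")

T0 = datetime(2020, 1, 1, 8, 0)


def make_trace(activities, case_id="c", start=None) -> Trace:
    """A trace with one complete-time event per activity, one minute apart."""
    base = start or T0
    return Trace(
        case_id,
        [
            Event(f"{case_id}-{i}", a, complete_time=base + timedelta(minutes=i))
            for i, a in enumerate(activities)
        ],
    )


@pytest.fixture(scope="session")
def stroke():
    from clindeclare.stroke_model import stroke_model

    return stroke_model()


@pytest.fixture(scope="session")
def demo_log():
    from clindeclare.stroke_model import demo_log

    return demo_log()


@pytest.fixture(scope="session")
def rules_by_id(stroke):
    return {g.rule_id: g for g in stroke.rules}


# --------------------------------------------------------------------------
# hypothesis strategies

_names = st.sampled_from(["alpha", "beta", "gamma", "score"])
_kinds = st.sampled_from(list(AttributeKind))
_datetimes = st.integers(min_value=0, max_value=500_000).map(
    lambda m: T0 + timedelta(minutes=m)
)
_values = st.one_of(
    st.booleans(),
    st.integers(min_value=-1000, max_value=1000),
    st.floats(allow_nan=False, allow_infinity=False, width=32),
    st.text(
        alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"), max_codepoint=0x24F),
        max_size=8,
    ),
    _datetimes,
)


@st.composite
def events(draw, index=0):
    has_start = draw(st.booleans())
    has_complete = draw(st.booleans()) or not has_start
    complete = draw(_datetimes) if has_complete else None
    if has_start:
        start = (complete - timedelta(minutes=draw(st.integers(0, 120)))
                 if complete is not None else draw(_datetimes))
    else:
        start = None
    attrs = {}
    for name in draw(st.lists(_names, unique=True, max_size=3)):
        kind = draw(_kinds)
        value = draw(_datetimes) if kind is AttributeKind.TIME else draw(_values)
        attrs[name] = ClinicalAttribute(name, kind, value)
    return Event(
        f"e{draw(st.integers(0, 10 ** 6))}-{index}",
        draw(st.sampled_from(["A", "T", "X", "Y"])),
        start_time=start,
        complete_time=complete,
        attributes=attrs,
    )


@st.composite
def traces(draw, case_id="c"):
    evs = [draw(events(index=i)) for i in range(draw(st.integers(0, 10)))]
    return Trace(case_id, evs)


@st.composite
def event_logs(draw):
    n = draw(st.integers(0, 10))
    return EventLog([draw(traces(case_id=f"case-{i}")) for i in range(n)])
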