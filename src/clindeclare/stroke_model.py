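"""Packaged process model for acute ischemic stroke thrombolysis care.

Five guideline-derived rules, transcribed in the constraint-tuple notation:

1. CT and blood glucose must both be tested before IV thrombolysis
   (conjunction: two sibling sub-rules 1.1 and 1.2 sharing rule label 1,
   each a plain precedence constraint).
2. Door-to-needle time (DNT) below 60 minutes:
   ``<precedence, admit, thrombolysis, psi(1,1)>`` with
   ``[complete time, complete time, 60, <]``.
3. Blood pressure below 180/100 mm Hg before the target activity:
   ``<precedence, vital_signs test, antipyretic, psi(3,.)>`` with
   ``[systolic pressure, 180, <]&[diastolic pressure, 100, <]``.
   (The printed target activity name "antipyretic" is kept verbatim even
   though the rule text concerns blood pressure before thrombolysis — the
   transcription follows the published table.)
4. No thrombolysis for patients on a treatment dose of low-molecular-weight
   heparin within the previous 24 h: a disjunction of
   ``<not_coexistence, heparin injection, thrombolysis>`` and
   ``<precedence, heparin injection, thrombolysis, psi(1,1)>`` with
   ``[complete time, start time, 24*60, >]`` (the dose was long enough ago).
5. Dispensing drugs must be double-checked by two different nurses:
   ``<existence, dispensing drugs, psi(6,6)>`` with
   ``[executor, proofreader, !=]`` — a self-correlation on the activated
   event's two action attributes.

These five rules are an illustration of the representation, not a complete
stroke guideline.
"""

from __future__ import annotations

from importlib import resources

from .constraint_model import ProcessModel, load_model, validate_against_dictionary
from .event_model import AttributeKind, EventLog, Trace, EventLog as _EventLog, read_csv_log

__all__ = [
    "stroke_model",
    "stroke_attribute_kinds",
    "ACTIVITY_ALIASES",
    "normalize_activities",
    "demo_log",
    "packaged_path",
]

#: attribute dictionary for the stroke model (name -> kind)
_ATTRIBUTE_KINDS = {
    "executor": AttributeKind.ACTION,
    "proofreader": AttributeKind.ACTION,
    "systolic pressure": AttributeKind.OBSERVATION,
    "diastolic pressure": AttributeKind.OBSERVATION,
    "blood glucose": AttributeKind.OBSERVATION,
    "patient name": AttributeKind.DEMOGRAPHY,
    "address": AttributeKind.DEMOGRAPHY,
    "diagnosis": AttributeKind.EVALUATION,
    "order": AttributeKind.INSTRUCTION,
    "drug": AttributeKind.ACTION,
    "cohort": AttributeKind.ADMIN,
    "ward": AttributeKind.ADMIN,
}

#: the demo log and the rule table spell several activities differently;
#: this map normalizes raw activity names onto the model alphabet
ACTIVITY_ALIASES = {
    "Admit": "admit",
    "CT examination": "CT examination",
    "MRI examination": "MRI examination",
    "Blood sugar test": "blood glucose test",
    "Blood glucose test": "blood glucose test",
    "Intravenous thrombolysis": "thrombolysis",
    "Statins drugs": "statins drugs",
    "Anticoagulant drugs": "anticoagulant drugs",
    "Antiplatelet drugs": "antiplatelet drugs",
    "Insulin injection": "insulin injection",
    "Have a fever": "have a fever",
    "Hypertensive": "hypertensive",
    "Discharge": "discharge",
    "Vital signs test": "vital_signs test",
    "Heparin injection": "heparin injection",
    "Dispensing drugs": "dispensing drugs",
    "Antipyretic": "antipyretic",
}


def stroke_attribute_kinds() -> dict[str, AttributeKind]:
    return dict(_ATTRIBUTE_KINDS)


def packaged_path(name: str):
    """Filesystem path of a packaged data file (stroke_model.json, stroke_demo.csv, stroke_demo.xes)."""
    return resources.files("clindeclare").joinpath("data").joinpath(name)


def stroke_model() -> ProcessModel:
    """Load and validate the packaged five-rule stroke model.

    Six rule groups (1.1, 1.2, 2, 3, 4, 5) holding seven constraint tuples;
    rule 4 is the only true disjunction.
    """
    with resources.as_file(packaged_path("stroke_model.json")) as path:
        model = load_model(path)
    validate_against_dictionary(model, _ATTRIBUTE_KINDS)
    return model


def normalize_activities(log: EventLog, aliases: dict[str, str] | None = None) -> EventLog:
    """Return a copy of the log with activity names mapped through the alias table."""
    from dataclasses import replace

    aliases = ACTIVITY_ALIASES if aliases is None else aliases
    traces = []
    for t in log:
        events = [replace(e, activity=aliases.get(e.activity, e.activity)) for e in t.events]
        traces.append(Trace(t.case_id, events, dict(t.attributes)))
    return _EventLog(traces)


def demo_log(normalized: bool = True) -> EventLog:
    """The packaged three-case demonstration log (18 events).

    Case 1 is a compliant thrombolysis episode (DNT 40 min), case 2 a
    non-thrombolysis episode, and case 3 a late thrombolysis (DNT 72 min).
    """
    with resources.as_file(packaged_path("stroke_demo.csv")) as path:
        log = read_csv_log(path, _ATTRIBUTE_KINDS)
    return normalize_activities(log) if normalized else log
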