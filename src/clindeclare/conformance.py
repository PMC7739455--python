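"""Event-by-event conformance checking of traces against constraints.

For each constraint the checker walks the trace once, collecting
*activations* (events that oblige the constraint to be checked), and
resolves every activation to *fulfilled* or *violated*.  A violation is
attributed to one of two result sections:

* ``control_flow`` — the required counterpart event (or occurrence count)
  is structurally absent / a forbidden counterpart is present;
* ``data_flow`` — counterpart events exist in the right position but none
  satisfies the data conditions, or the activated event itself fails a
  self-condition.

A constraint is satisfied on a trace iff it has no violated activations and
its control-flow section holds; a constraint with no activations whose
control-flow section holds is *vacuously* satisfied.

Activation mapping (per template): response-like templates and the
existence family activate on source (A) events; precedence-like templates
activate on target (T) events, each of which must find a qualifying prior
source; negative-relation templates activate on A events; choice templates
are trace-level with a single synthetic activation.  An activation is
fulfilled by the nearest qualifying counterpart in the required direction,
and one counterpart may fulfil many activations.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field
from enum import Enum

from .constraint_model import (
    ConditionAtom,
    ConditionRole,
    ConstantAtom,
    ConstraintTuple,
    DataCondition,
    DiffAtom,
    PairAtom,
    ProcessModel,
    RuleGroup,
    Side,
)
from .errors import ClinDeclareWarning
from .event_model import Event, EventLog, Trace
from .templates import TemplateFamily, TemplateKind

__all__ = [
    "Status",
    "FailureSection",
    "ActivationRecord",
    "TraceResult",
    "GroupTraceResult",
    "CaseOutcome",
    "LogReport",
    "check_trace",
    "check_rulegroup",
    "check_log",
]


class Status(str, Enum):
    PENDING = "pending"
    FULFILLED = "fulfilled"
    VIOLATED = "violated"


class FailureSection(str, Enum):
    NONE = "none"
    CONTROL_FLOW = "control_flow"
    DATA_FLOW = "data_flow"


@dataclass
class ActivationRecord:
    constraint_id: str
    event: Event | None                 # None for the synthetic choice activation
    status: Status = Status.PENDING
    target: Event | None = None
    section: FailureSection = FailureSection.NONE
    failing_atom: ConditionAtom | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.status is Status.FULFILLED and self.section is not FailureSection.NONE:
            raise ValueError("fulfilled activation cannot carry a failure section")


@dataclass
class TraceResult:
    """Outcome of one constraint on one trace."""

    constraint: ConstraintTuple
    case_id: str
    activations: list[ActivationRecord] = field(default_factory=list)
    control_flow_ok: bool = True

    @property
    def fulfillments(self) -> list[ActivationRecord]:
        return [r for r in self.activations if r.status is Status.FULFILLED]

    @property
    def violations(self) -> list[ActivationRecord]:
        return [r for r in self.activations if r.status is Status.VIOLATED]

    @property
    def satisfied(self) -> bool:
        return self.control_flow_ok and not self.violations

    @property
    def vacuous(self) -> bool:
        return not self.activations and self.control_flow_ok


# --------------------------------------------------------------------------
# condition evaluation


def _attr_value(event: Event, name: str):
    return event.get(name)


def _eval_atom(atom: ConditionAtom, src: Event | None, tgt: Event | None):
    """Evaluate one atom; returns (holds, note_or_None).

    A referenced attribute missing from the involved event makes the atom
    false and attaches a "missing attribute" note instead of raising.
    """
    if isinstance(atom, DiffAtom):
        assert src is not None and tgt is not None
        ta = _attr_value(src, atom.time_attr_a)
        tb = _attr_value(tgt, atom.time_attr_t)
        if ta is None:
            return False, f"missing attribute {atom.time_attr_a!r} on {src.activity!r}"
        if tb is None:
            return False, f"missing attribute {atom.time_attr_t!r} on {tgt.activity!r}"
        minutes = (tb - ta).total_seconds() / 60.0
        return atom.op.apply(minutes, atom.threshold_minutes), None
    if isinstance(atom, PairAtom):
        assert src is not None and tgt is not None
        va = _attr_value(src, atom.name_a)
        vb = _attr_value(tgt, atom.name_t)
        if va is None:
            return False, f"missing attribute {atom.name_a!r} on {src.activity!r}"
        if vb is None:
            return False, f"missing attribute {atom.name_t!r} on {tgt.activity!r}"
        return atom.op.apply(va, vb), None
    # ConstantAtom
    event = src if atom.side in (Side.SOURCE, Side.SELF) else tgt
    assert event is not None
    value = _attr_value(event, atom.name)
    if value is None:
        return False, f"missing attribute {atom.name!r} on {event.activity!r}"
    return atom.op.apply(value, atom.constant), None


def _eval_condition(cond: DataCondition, src: Event | None, tgt: Event | None):
    """Conjunction over atoms; returns (holds, failing_atom, notes)."""
    notes: list[str] = []
    for atom in cond.atoms:
        ok, note = _eval_atom(atom, src, tgt)
        if note:
            notes.append(note)
        if not ok:
            return False, atom, tuple(notes)
    return True, None, tuple(notes)


def _split_psi(c: ConstraintTuple):
    activation = [p for p in c.psi if p.role is ConditionRole.ACTIVATION]
    target = [p for p in c.psi if p.role is ConditionRole.TARGET]
    correlation = [p for p in c.psi if p.role is ConditionRole.CORRELATION]
    return activation, target, correlation


def _eval_all(conds, src, tgt):
    notes: list[str] = []
    for cond in conds:
        ok, atom, nts = _eval_condition(cond, src, tgt)
        notes.extend(nts)
        if not ok:
            return False, atom, tuple(notes)
    return True, None, tuple(notes)


# --------------------------------------------------------------------------
# template-specific activation/matching logic

_A_ACTIVATED = {
    TemplateKind.RESPONDED_EXISTENCE,
    TemplateKind.RESPONSE,
    TemplateKind.ALTERNATE_RESPONSE,
    TemplateKind.CHAIN_RESPONSE,
    TemplateKind.NOT_COEXISTENCE,
    TemplateKind.NOT_SUCCESSION,
    TemplateKind.NOT_CHAIN_SUCCESSION,
}
_T_ACTIVATED = {
    TemplateKind.PRECEDENCE,
    TemplateKind.ALTERNATE_PRECEDENCE,
    TemplateKind.CHAIN_PRECEDENCE,
}


def check_trace(trace: Trace, c: ConstraintTuple) -> TraceResult:
    """Check one constraint on one trace: gate each activation on its own
    conditions, search counterparts in the template's direction, filter them
    by counterpart and correlation conditions, then resolve the activation
    to fulfilled or violated."""
    family = c.template.family
    if family is TemplateFamily.EXISTENCE:
        return _check_existence(trace, c)
    if family is TemplateFamily.CHOICE:
        return _check_choice(trace, c)
    if c.template in _A_ACTIVATED:
        return _check_source_activated(trace, c)
    if c.template in _T_ACTIVATED:
        return _check_target_activated(trace, c)
    raise NotImplementedError(f"template {c.template.value} has no checker")


def _check_existence(trace: Trace, c: ConstraintTuple) -> TraceResult:
    res = TraceResult(c, trace.case_id)
    events = [e for e in trace.events if e.activity == c.a]
    count = len(events)
    k = c.template
    if k is TemplateKind.EXISTENCE:
        res.control_flow_ok = count >= 1
    elif k is TemplateKind.ABSENCE:
        res.control_flow_ok = count == 0
    elif k is TemplateKind.EXISTENCE_N:
        res.control_flow_ok = count >= (c.n or 0)
    elif k is TemplateKind.ABSENCE_N:
        res.control_flow_ok = count <= (c.n or 0)
    else:  # EXACTLY_N
        res.control_flow_ok = count == (c.n or 0)
    # every A event is an activation whose own data conditions must hold;
    # correlation conditions of a unary constraint bind both sides to it
    for e in events:
        rec = ActivationRecord(c.cid, e)
        ok, atom, notes = _eval_all(c.psi, e, e)
        rec.notes = notes
        if ok:
            rec.status = Status.FULFILLED
        else:
            rec.status = Status.VIOLATED
            rec.section = FailureSection.DATA_FLOW
            rec.failing_atom = atom
        res.activations.append(rec)
    return res


def _check_choice(trace: Trace, c: ConstraintTuple) -> TraceResult:
    res = TraceResult(c, trace.case_id)
    act_conds, tgt_conds, corr = _split_psi(c)
    a_events = [
        e for e in trace.events
        if e.activity == c.a and _eval_all(act_conds, e, None)[0]
    ]
    t_events = [
        e for e in trace.events
        if e.activity == c.t and _eval_all(tgt_conds, None, e)[0]
    ]
    rec = ActivationRecord(c.cid, None)  # single synthetic trace-level activation
    has_a, has_t = bool(a_events), bool(t_events)
    if c.template is TemplateKind.CHOICE:
        ok = has_a or has_t
    else:  # EXCLUSIVE_CHOICE
        ok = has_a != has_t
    if ok:
        rec.status = Status.FULFILLED
        rec.target = (a_events or t_events)[0]
    else:
        rec.status = Status.VIOLATED
        rec.section = FailureSection.CONTROL_FLOW
        res.control_flow_ok = False
    res.activations.append(rec)
    return res


def _check_source_activated(trace: Trace, c: ConstraintTuple) -> TraceResult:
    """Templates activated on A events (response family and negative relations)."""
    res = TraceResult(c, trace.case_id)
    act_conds, tgt_conds, corr = _split_psi(c)
    events = trace.events
    a_pos = [i for i, e in enumerate(events) if e.activity == c.a]
    negative = c.template.family is TemplateFamily.NEGATIVE_RELATION

    for i in a_pos:
        src = events[i]
        ok, _, gate_notes = _eval_all(act_conds, src, None)
        if not ok:
            continue  # activation condition not met: the event does not activate
        rec = ActivationRecord(c.cid, src, notes=gate_notes)
        scope = _counterpart_scope(c.template, events, a_pos, i, c.t or "")
        match, failing_atom, candidate_seen, notes = _find_qualifying(
            scope, tgt_conds, corr, src, direction="forward"
        )
        rec.notes += notes
        if negative:
            if match is None:
                rec.status = Status.FULFILLED
            else:
                rec.status = Status.VIOLATED
                rec.section = FailureSection.CONTROL_FLOW
                rec.target = match
                res.control_flow_ok = False
        else:
            if match is not None:
                rec.status = Status.FULFILLED
                rec.target = match
            else:
                rec.status = Status.VIOLATED
                if candidate_seen:
                    rec.section = FailureSection.DATA_FLOW
                    rec.failing_atom = failing_atom
                else:
                    rec.section = FailureSection.CONTROL_FLOW
                    res.control_flow_ok = False
        res.activations.append(rec)
    return res


def _counterpart_scope(
    kind: TemplateKind, events: list[Event], a_pos: list[int], i: int, t: str
) -> list[Event]:
    """Candidate counterparts for an A activation at position i, nearest first."""
    n = len(events)
    if kind is TemplateKind.RESPONDED_EXISTENCE:
        order = list(range(i + 1, n)) + list(range(i - 1, -1, -1))
        return [events[j] for j in order if events[j].activity == t]
    if kind is TemplateKind.RESPONSE or kind is TemplateKind.NOT_SUCCESSION:
        return [events[j] for j in range(i + 1, n) if events[j].activity == t]
    if kind is TemplateKind.ALTERNATE_RESPONSE:
        nxt = next((j for j in a_pos if j > i), n)
        return [events[j] for j in range(i + 1, nxt) if events[j].activity == t]
    if kind in (TemplateKind.CHAIN_RESPONSE, TemplateKind.NOT_CHAIN_SUCCESSION):
        return [events[i + 1]] if i + 1 < n and events[i + 1].activity == t else []
    if kind is TemplateKind.NOT_COEXISTENCE:
        return [e for e in events if e.activity == t]
    raise NotImplementedError(kind)


def _check_target_activated(trace: Trace, c: ConstraintTuple) -> TraceResult:
    """Precedence-family templates: every T event must find a qualifying prior A."""
    res = TraceResult(c, trace.case_id)
    act_conds, tgt_conds, corr = _split_psi(c)
    events = trace.events
    t_pos = [i for i, e in enumerate(events) if e.activity == c.t]

    for i in t_pos:
        tgt = events[i]
        ok, _, gate_notes = _eval_all(tgt_conds, None, tgt)
        if not ok:
            continue  # the target-side condition gates activation of the T event
        rec = ActivationRecord(c.cid, tgt, notes=gate_notes)
        if c.template is TemplateKind.PRECEDENCE:
            scope_idx = range(i - 1, -1, -1)
        elif c.template is TemplateKind.ALTERNATE_PRECEDENCE:
            prev_t = max((j for j in t_pos if j < i), default=-1)
            scope_idx = range(i - 1, prev_t, -1)
        else:  # CHAIN_PRECEDENCE
            scope_idx = range(i - 1, i - 2, -1) if i >= 1 else range(0)
        scope = [events[j] for j in scope_idx if events[j].activity == c.a]
        match, failing_atom, candidate_seen, notes = _find_qualifying(
            scope, act_conds, corr, tgt, direction="backward"
        )
        rec.notes += notes
        if match is not None:
            rec.status = Status.FULFILLED
            rec.target = match
        else:
            rec.status = Status.VIOLATED
            if candidate_seen:
                rec.section = FailureSection.DATA_FLOW
                rec.failing_atom = failing_atom
            else:
                rec.section = FailureSection.CONTROL_FLOW
                res.control_flow_ok = False
        res.activations.append(rec)
    return res


def _find_qualifying(scope, side_conds, corr_conds, anchor, direction):
    """Scan candidate counterparts (nearest first) for one satisfying the
    counterpart-side and correlation conditions.

    ``anchor`` is the activating event; for ``forward`` templates it is the
    source A and candidates are targets, for ``backward`` (precedence-like)
    it is the target T and candidates are sources.
    """
    failing_atom = None
    notes: list[str] = []
    for cand in scope:
        if direction == "forward":
            src, tgt = anchor, cand
        else:
            src, tgt = cand, anchor
        ok1, atom1, n1 = _eval_all(side_conds, src, tgt)
        ok2, atom2, n2 = _eval_all(corr_conds, src, tgt) if ok1 else (True, None, ())
        notes.extend(n1)
        notes.extend(n2)
        if ok1 and ok2:
            return cand, None, True, tuple(notes)
        if failing_atom is None:
            failing_atom = atom1 if not ok1 else atom2
    return None, failing_atom, bool(scope), tuple(notes)


# --------------------------------------------------------------------------
# rule groups and whole logs


@dataclass
class GroupTraceResult:
    """Outcome of a rule group (disjunction of constraints) on one trace."""

    group: RuleGroup
    case_id: str
    branch_results: list[TraceResult]
    best: TraceResult

    @property
    def satisfied(self) -> bool:
        return any(r.satisfied for r in self.branch_results)

    @property
    def vacuous(self) -> bool:
        return self.best.vacuous

    @property
    def outcome(self) -> str:
        if not self.satisfied:
            return "violated"
        return "vacuous" if self.best.vacuous else "fulfilled"


def check_rulegroup(trace: Trace, g: RuleGroup) -> GroupTraceResult:
    """A group is satisfied iff ANY member constraint is satisfied; the
    reported detail is the best branch (first satisfied branch, else the
    branch with fewest violations, first listed on ties)."""
    results = [check_trace(trace, c) for c in g.constraints]
    best = next((r for r in results if r.satisfied), None)
    if best is None:
        best = min(results, key=lambda r: len(r.violations))
    return GroupTraceResult(g, trace.case_id, results, best)


@dataclass
class CaseOutcome:
    case_id: str
    rule_id: str
    outcome: str  # fulfilled | violated | vacuous
    cohort: str
    mandatory: bool
    detail: GroupTraceResult


@dataclass
class LogReport:
    """Aggregated conformance results of a model over a log.

    ``counts`` are case-level per rule (and per cohort tag when traces carry
    one); in the printable-table layout the fulfilled column absorbs the
    vacuously satisfied cases so the two columns sum to the cohort size.
    """

    model_name: str
    n_traces: int
    outcomes: list[CaseOutcome]
    cohorts: list[str]

    def counts(self, rule_id: str, cohort: str | None = None) -> dict[str, int]:
        out = {"violated": 0, "fulfilled": 0, "vacuous": 0}
        for o in self.outcomes:
            if o.rule_id == rule_id and (cohort is None or o.cohort == cohort):
                out[o.outcome] += 1
        return out

    @property
    def rule_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for o in self.outcomes:
            seen.setdefault(o.rule_id, None)
        return list(seen)

    @property
    def violated_case_ids(self) -> list[str]:
        """Cases violating at least one mandatory rule (the headline count)."""
        seen: dict[str, None] = {}
        for o in self.outcomes:
            if o.outcome == "violated" and o.mandatory:
                seen.setdefault(o.case_id, None)
        return list(seen)

    def deviations(self) -> list[dict]:
        """Flat records of every violated activation, for inspection."""
        rows: list[dict] = []
        for o in self.outcomes:
            if o.outcome != "violated":
                continue
            for rec in o.detail.best.violations:
                rows.append(
                    {
                        "case_id": o.case_id,
                        "rule_id": o.rule_id,
                        "constraint": o.detail.best.constraint.cid,
                        "event_id": rec.event.event_id if rec.event else "",
                        "activity": rec.event.activity if rec.event else "",
                        "section": rec.section.value,
                        "failing_atom": _atom_text(rec.failing_atom),
                        "notes": "; ".join(rec.notes),
                    }
                )
            if not o.detail.best.violations:
                rows.append(
                    {
                        "case_id": o.case_id,
                        "rule_id": o.rule_id,
                        "constraint": o.detail.best.constraint.cid,
                        "event_id": "",
                        "activity": "",
                        "section": "control_flow",
                        "failing_atom": "",
                        "notes": "trace-level control-flow failure",
                    }
                )
        return rows

    def event_totals(self) -> dict[str, dict[str, int]]:
        """Per-rule event-level totals over best branches."""
        totals: dict[str, dict[str, int]] = {}
        for o in self.outcomes:
            t = totals.setdefault(
                o.rule_id, {"activations": 0, "fulfillments": 0, "violations": 0}
            )
            t["activations"] += len(o.detail.best.activations)
            t["fulfillments"] += len(o.detail.best.fulfillments)
            t["violations"] += len(o.detail.best.violations)
        return totals

    # ---- output renderings

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "n_traces": self.n_traces,
            "cohorts": self.cohorts,
            "rules": {
                rid: {
                    "per_cohort": {c: self.counts(rid, c) for c in self.cohorts},
                    "total": self.counts(rid),
                    "events": self.event_totals().get(rid, {}),
                }
                for rid in self.rule_ids
            },
            "violated_cases": self.violated_case_ids,
            "case_outcomes": [
                {
                    "case_id": o.case_id,
                    "rule_id": o.rule_id,
                    "outcome": o.outcome,
                    "cohort": o.cohort,
                    "mandatory": o.mandatory,
                }
                for o in self.outcomes
            ],
            "deviations": self.deviations(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, ensure_ascii=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def to_csv(self, path=None) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["case_id", "rule_id", "outcome", "cohort", "mandatory"])
        for o in self.outcomes:
            writer.writerow([o.case_id, o.rule_id, o.outcome, o.cohort, o.mandatory])
        text = buf.getvalue()
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def format_table(self) -> str:
        """Console table: one row per rule, Vio/Ful columns per cohort.

        The Ful column counts fulfilled plus vacuously satisfied cases, so
        Vio + Ful equals the cohort size on every row.
        """
        cohorts = self.cohorts or ["all"]
        header = ["No", "Description"]
        for c in cohorts:
            header += [f"{c} Vio", f"{c} Ful"]
        rows = [header]
        desc = {o.rule_id: o.detail.group.description for o in self.outcomes}
        for rid in self.rule_ids:
            row = [rid, desc.get(rid, "")]
            for c in cohorts:
                n = self.counts(rid, c) if self.cohorts else self.counts(rid)
                row += [str(n["violated"]), str(n["fulfilled"] + n["vacuous"])]
            rows.append(row)
        widths = [max(len(r[k]) for r in rows) for k in range(len(header))]
        lines = []
        for r in rows:
            lines.append("  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip())
        lines.insert(1, "-" * max(len(l) for l in lines))
        return "\n".join(lines)


def _atom_text(atom: ConditionAtom | None) -> str:
    if atom is None:
        return ""
    from .constraint_model import _format_atom

    return _format_atom(atom)


def check_log(log: EventLog, model: ProcessModel, cohort_attribute: str = "cohort") -> LogReport:
    """Check every rule group of the model against every trace of the log.

    Activities referenced by the model but absent from the whole log trigger
    a warning; the affected rules are still evaluated (vacuously where
    applicable).  Optional (non-mandatory) rules are reported but never flip
    a case into the headline violated set.
    """
    present = log.alphabet
    missing = sorted(
        {
            act
            for g in model.rules
            for c in g.constraints
            for act in (c.a, c.t)
            if act and act not in present
        }
    )
    if missing and len(log) > 0:
        warnings.warn(
            f"model activities never occur in the log: {', '.join(missing)}",
            ClinDeclareWarning,
            stacklevel=2,
        )
    outcomes: list[CaseOutcome] = []
    cohorts: dict[str, None] = {}
    for trace in log:
        cohort = str(trace.attributes.get(cohort_attribute, "")) or "all"
        cohorts.setdefault(cohort, None)
        for g in model.rules:
            gr = check_rulegroup(trace, g)
            outcomes.append(
                CaseOutcome(trace.case_id, g.rule_id, gr.outcome, cohort, g.mandatory, gr)
            )
    return LogReport(model.name, len(log), outcomes, list(cohorts))
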