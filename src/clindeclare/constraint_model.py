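"""Multi-perspective constraint representation.

A constraint is a tuple ``<template, A, T, psi>``: a Declare template over a
source activity A and (for binary templates) a target activity T, decorated
with data conditions ``psi``.  Conditions come in three roles:

* activation ``psi(i,.)`` — a condition on attributes of A only,
* target ``psi(.,j)`` — a condition on attributes of T only,
* correlation ``psi(i,j)`` — a condition relating attributes of A and T
  (for unary constraints both sides bind to the single activated event).

``i`` and ``j`` are attribute-kind indices (1..7); arranging the conditions
of one constraint by these indices yields its constrained-relationship
matrix.  Each condition is a conjunction of atoms written in bracket
notation, e.g. ``[systolic pressure, 180, <]&[diastolic pressure, 100, <]``
or, for a timestamp difference in minutes,
``[complete time, start time, 24*60, >]``.
"""

from __future__ import annotations

import ast
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .errors import ConditionParseError, ModelError
from .event_model import AttributeKind, COMPLETE_TIME, START_TIME
from .templates import TemplateKind

__all__ = [
    "Op",
    "Side",
    "ConditionRole",
    "ConstantAtom",
    "PairAtom",
    "DiffAtom",
    "ConditionAtom",
    "DataCondition",
    "ConstraintTuple",
    "RuleGroup",
    "ProcessModel",
    "ConstrainedRelationshipMatrix",
    "parse_condition",
    "format_condition",
    "build_matrix",
    "load_model",
    "save_model",
    "model_to_dict",
    "model_from_dict",
]


class Op(str, Enum):
    EQ = "="
    NE = "!="
    LT = "<"
    GT = ">"
    LE = "<="
    GE = ">="

    def apply(self, x, y) -> bool:
        try:
            if self is Op.EQ:
                return x == y
            if self is Op.NE:
                return x != y
            if self is Op.LT:
                return x < y
            if self is Op.GT:
                return x > y
            if self is Op.LE:
                return x <= y
            return x >= y
        except TypeError:
            return False


_OP_ALIASES = {
    "=": Op.EQ, "==": Op.EQ,
    "!=": Op.NE, "! =": Op.NE, "≠": Op.NE, "<>": Op.NE,
    "<": Op.LT, ">": Op.GT,
    "<=": Op.LE, "≤": Op.LE, "=<": Op.LE,
    ">=": Op.GE, "≥": Op.GE, "=>": Op.GE,
}


def _parse_op(token: str) -> Op:
    key = " ".join(token.split())
    try:
        return _OP_ALIASES[key]
    except KeyError:
        raise ConditionParseError(f"unknown operator: {token!r}") from None


class Side(str, Enum):
    SOURCE = "source"
    TARGET = "target"
    SELF = "self"


class ConditionRole(str, Enum):
    ACTIVATION = "activation"   # psi(i,.)
    TARGET = "target"           # psi(.,j)
    CORRELATION = "correlation" # psi(i,j)


@dataclass(frozen=True)
class ConstantAtom:
    """``[attr, constant, op]`` — attribute value compared with a constant."""

    name: str
    op: Op
    constant: float | int | str
    constant_text: str = ""
    side: Side = Side.SOURCE

    def __post_init__(self):
        if not self.constant_text:
            object.__setattr__(self, "constant_text", _const_text(self.constant))


@dataclass(frozen=True)
class PairAtom:
    """``[attr_A, attr_T, op]`` — two attribute values compared with each other."""

    name_a: str
    name_t: str
    op: Op


@dataclass(frozen=True)
class DiffAtom:
    """``[time_A, time_T, threshold, op]`` — (T.time - A.time) in minutes vs threshold."""

    time_attr_a: str
    time_attr_t: str
    threshold_minutes: float
    op: Op
    threshold_text: str = ""

    def __post_init__(self):
        if not self.threshold_text:
            object.__setattr__(self, "threshold_text", _const_text(self.threshold_minutes))


ConditionAtom = ConstantAtom | PairAtom | DiffAtom


@dataclass(frozen=True)
class DataCondition:
    """An ordered conjunction of atoms with a role and its kind indices.

    The empty conjunction is the NULL condition and always holds.
    """

    atoms: tuple[ConditionAtom, ...]
    role: ConditionRole
    i: AttributeKind | None = None
    j: AttributeKind | None = None

    def __post_init__(self):
        if self.role is ConditionRole.ACTIVATION and (self.i is None or self.j is not None):
            raise ModelError("activation condition psi(i,.) needs i and no j")
        if self.role is ConditionRole.TARGET and (self.j is None or self.i is not None):
            raise ModelError("target condition psi(.,j) needs j and no i")
        if self.role is ConditionRole.CORRELATION and (self.i is None or self.j is None):
            raise ModelError("correlation condition psi(i,j) needs both i and j")

    @property
    def is_null(self) -> bool:
        return not self.atoms


# --------------------------------------------------------------------------
# bracket-notation parsing


def _const_text(value) -> str:
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


_NUM_EXPR_RE = re.compile(r"^[\d\s.+\-*/()]+$")


def _eval_numeric(text: str) -> float | int | None:
    """Evaluate a constant arithmetic expression like ``24*60``; None if not numeric."""
    text = text.strip()
    if not text or not _NUM_EXPR_RE.match(text):
        return None
    try:
        node = ast.parse(text, mode="eval")
    except SyntaxError:
        return None

    def ev(n):
        if isinstance(n, ast.Expression):
            return ev(n.body)
        if isinstance(n, ast.Constant) and isinstance(n.value, (int, float)):
            return n.value
        if isinstance(n, ast.BinOp) and isinstance(n.op, (ast.Add, ast.Sub, ast.Mult, ast.Div)):
            a, b = ev(n.left), ev(n.right)
            if isinstance(n.op, ast.Add):
                return a + b
            if isinstance(n.op, ast.Sub):
                return a - b
            if isinstance(n.op, ast.Mult):
                return a * b
            return a / b
        if isinstance(n, ast.UnaryOp) and isinstance(n.op, (ast.USub, ast.UAdd)):
            v = ev(n.operand)
            return -v if isinstance(n.op, ast.USub) else v
        raise ConditionParseError(f"unsupported arithmetic in constant: {text!r}")

    try:
        return ev(node)
    except ConditionParseError:
        return None


_BRACKET_RE = re.compile(r"\[([^\[\]]*)\]")


def parse_condition(
    text: str,
    i: AttributeKind | int | None = None,
    j: AttributeKind | int | None = None,
) -> DataCondition:
    """Parse ``&``-joined bracket atoms into a typed :class:`DataCondition`.

    The role is inferred from which kind indices are given: (i,.) activation,
    (.,j) target, (i,j) correlation.  Atom shapes:

    * ``[x, c, op]`` with numeric/arithmetic ``c`` or a quoted string — ConstantAtom
    * ``[x, y, op]`` — PairAtom
    * ``[x, y, c, op]`` — DiffAtom ((T.y − A.x) in minutes compared to c)
    """
    i = AttributeKind(i) if i is not None else None
    j = AttributeKind(j) if j is not None else None
    if i is not None and j is not None:
        role = ConditionRole.CORRELATION
    elif i is not None:
        role = ConditionRole.ACTIVATION
    elif j is not None:
        role = ConditionRole.TARGET
    else:
        raise ModelError("a data condition needs at least one kind index (i and/or j)")

    text = text.strip()
    atoms: list[ConditionAtom] = []
    if text:
        remainder = text
        for m in _BRACKET_RE.finditer(text):
            atoms.append(_parse_atom(m.group(1), role, i, j))
            remainder = remainder.replace(m.group(0), "", 1)
        if remainder.strip().strip("&").strip():
            raise ConditionParseError(f"malformed condition text: {text!r}")
        if not atoms:
            raise ConditionParseError(f"no bracket atoms found in: {text!r}")
    return DataCondition(tuple(atoms), role, i, j)


def _parse_atom(
    body: str, role: ConditionRole, i: AttributeKind | None, j: AttributeKind | None
) -> ConditionAtom:
    parts = [p.strip() for p in body.split(",")]
    if len(parts) == 4:
        x, y, c, op_tok = parts
        value = _eval_numeric(c)
        if value is None:
            raise ConditionParseError(f"non-numeric threshold {c!r} in [{body}]")
        if i is not AttributeKind.TIME or j is not AttributeKind.TIME:
            raise ModelError(
                f"timestamp-difference atom [{body}] requires kind indices (1,1) = (time,time)"
            )
        return DiffAtom(x, y, float(value), _parse_op(op_tok), threshold_text=c.strip())
    if len(parts) == 3:
        x, y, op_tok = parts
        op = _parse_op(op_tok)
        value = _eval_numeric(y)
        if value is not None:
            return ConstantAtom(x, op, value, constant_text=y.strip(), side=_const_side(role))
        if len(y) >= 2 and y[0] == y[-1] and y[0] in "'\"":
            return ConstantAtom(x, op, y[1:-1], constant_text=y, side=_const_side(role))
        if role is ConditionRole.CORRELATION:
            return PairAtom(x, y, op)
        # single-sided condition comparing to a bare string constant
        return ConstantAtom(x, op, y, constant_text=y, side=_const_side(role))
    raise ConditionParseError(f"bracket atom needs 3 or 4 comma-separated parts: [{body}]")


def _const_side(role: ConditionRole) -> Side:
    if role is ConditionRole.TARGET:
        return Side.TARGET
    if role is ConditionRole.CORRELATION:
        return Side.SOURCE
    return Side.SOURCE


def format_condition(cond: DataCondition) -> str:
    """Serialize back to bracket notation (canonical ``, `` separators)."""
    return "&".join(_format_atom(a) for a in cond.atoms)


def _format_atom(atom: ConditionAtom) -> str:
    if isinstance(atom, DiffAtom):
        return f"[{atom.time_attr_a}, {atom.time_attr_t}, {atom.threshold_text}, {atom.op.value}]"
    if isinstance(atom, PairAtom):
        return f"[{atom.name_a}, {atom.name_t}, {atom.op.value}]"
    return f"[{atom.name}, {atom.constant_text}, {atom.op.value}]"


# --------------------------------------------------------------------------
# constraint tuples, rule groups, models


@dataclass(frozen=True)
class ConstraintTuple:
    """``c = <template, A, T, psi>`` plus the mandatory/optional flag."""

    template: TemplateKind
    a: str
    t: str | None = None
    psi: tuple[DataCondition, ...] = ()
    mandatory: bool = True
    n: int | None = None
    cid: str = ""

    def __post_init__(self):
        if not self.a:
            raise ModelError("constraint must name a source activity A")
        if self.template.is_binary and not self.t:
            raise ModelError(f"binary template {self.template.value} requires a target activity T")
        if self.template.takes_count and (self.n is None or self.n < 0):
            raise ModelError(f"template {self.template.value} requires n >= 0")
        if not self.cid:
            label = f"{self.template.value}({self.a}" + (f", {self.t})" if self.t else ")")
            object.__setattr__(self, "cid", label)
        if not self.template.is_binary:
            for cond in self.psi:
                if cond.role is ConditionRole.TARGET:
                    raise ModelError(
                        f"unary constraint {self.cid} cannot carry a target condition psi(.,j)"
                    )


@dataclass(frozen=True)
class RuleGroup:
    """A disjunction (any_of) of constraint tuples under one human-readable rule.

    A single-member group is an ordinary constraint.  ``label`` groups
    sub-rules that stem from one guideline sentence (e.g. 1.1 and 1.2 both
    carry label "1").
    """

    rule_id: str
    description: str
    constraints: tuple[ConstraintTuple, ...]
    mandatory: bool = True
    label: str = ""

    def __post_init__(self):
        if not self.constraints:
            raise ModelError(f"rule {self.rule_id}: empty constraint disjunction")
        if not self.label:
            object.__setattr__(self, "label", self.rule_id.split(".")[0])


@dataclass(frozen=True)
class ProcessModel:
    name: str
    alphabet: frozenset[str]
    rules: tuple[RuleGroup, ...]

    def __post_init__(self):
        for g in self.rules:
            for c in g.constraints:
                for act in (c.a, c.t):
                    if act and act not in self.alphabet:
                        raise ModelError(
                            f"rule {g.rule_id}: activity {act!r} not in the model alphabet"
                        )

    def constraints(self) -> list[ConstraintTuple]:
        return [c for g in self.rules for c in g.constraints]


# --------------------------------------------------------------------------
# constrained-relationship matrix


@dataclass(frozen=True)
class ConstrainedRelationshipMatrix:
    """The 7x7 kind-indexed grid of one constraint's conditions.

    Correlation conditions occupy cell ``(i, j)``; activation conditions the
    marginal row ``(i, None)`` and target conditions the marginal column
    ``(None, j)``.  Absent cells are NULL.
    """

    cells: Mapping[tuple[AttributeKind | None, AttributeKind | None], DataCondition]

    def cell(self, i: AttributeKind | None, j: AttributeKind | None) -> DataCondition | None:
        return self.cells.get((i, j))

    def flatten(self) -> list[DataCondition]:
        return list(self.cells.values())


def build_matrix(c: ConstraintTuple) -> ConstrainedRelationshipMatrix:
    """Place each condition of ``c`` in its (i, j) cell; same-cell conditions
    are merged by conjunction (atom lists concatenated in order)."""
    cells: dict[tuple[AttributeKind | None, AttributeKind | None], DataCondition] = {}
    for cond in c.psi:
        key = (cond.i, cond.j)
        if key in cells:
            prev = cells[key]
            cells[key] = DataCondition(prev.atoms + cond.atoms, cond.role, cond.i, cond.j)
        else:
            cells[key] = cond
    return ConstrainedRelationshipMatrix(cells)


# --------------------------------------------------------------------------
# JSON model files


def model_to_dict(m: ProcessModel) -> dict:
    rules = []
    for g in m.rules:
        rules.append(
            {
                "id": g.rule_id,
                **({"label": g.label} if g.label != g.rule_id.split(".")[0] else {}),
                "description": g.description,
                "mandatory": g.mandatory,
                "any_of": [
                    {
                        "template": c.template.value,
                        "A": c.a,
                        **({"T": c.t} if c.t else {}),
                        **({"n": c.n} if c.n is not None else {}),
                        "psi": [
                            {
                                **({"i": int(cond.i)} if cond.i is not None else {}),
                                **({"j": int(cond.j)} if cond.j is not None else {}),
                                "text": format_condition(cond),
                            }
                            for cond in c.psi
                        ],
                    }
                    for c in g.constraints
                ],
            }
        )
    return {"name": m.name, "alphabet": sorted(m.alphabet), "rules": rules}


def model_from_dict(data: Mapping) -> ProcessModel:
    if not isinstance(data, Mapping):
        raise ModelError("model file must contain a JSON object")
    for key in ("name", "alphabet", "rules"):
        if key not in data:
            raise ModelError(f"model: missing required key {key!r}")
    alphabet = frozenset(str(a) for a in data["alphabet"])
    rules: list[RuleGroup] = []
    for rn, rule in enumerate(data["rules"], start=1):
        path = f"rules[{rn - 1}]"
        if "any_of" not in rule or not rule["any_of"]:
            raise ModelError(f"{path}: missing or empty 'any_of'")
        rid = str(rule.get("id") or rn)
        mandatory = bool(rule.get("mandatory", True))
        constraints: list[ConstraintTuple] = []
        for cn, cd in enumerate(rule["any_of"]):
            cpath = f"{path}.any_of[{cn}]"
            try:
                template = TemplateKind(cd["template"])
            except (KeyError, ValueError):
                raise ModelError(f"{cpath}: unknown or missing template") from None
            psi = []
            for pd in cd.get("psi", []):
                try:
                    psi.append(parse_condition(pd.get("text", ""), pd.get("i"), pd.get("j")))
                except (ConditionParseError, ModelError, ValueError) as exc:
                    raise ModelError(f"{cpath}.psi: {exc}") from None
            constraints.append(
                ConstraintTuple(
                    template=template,
                    a=str(cd.get("A", "")),
                    t=cd.get("T"),
                    psi=tuple(psi),
                    mandatory=mandatory,
                    n=cd.get("n"),
                    cid=f"{rid}.{cn + 1}" if len(rule["any_of"]) > 1 else rid,
                )
            )
        rules.append(
            RuleGroup(
                rule_id=rid,
                description=str(rule.get("description", "")),
                constraints=tuple(constraints),
                mandatory=mandatory,
                label=str(rule.get("label", "")),
            )
        )
    return ProcessModel(str(data["name"]), alphabet, tuple(rules))


def load_model(path) -> ProcessModel:
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelError(f"{path}: invalid JSON ({exc})") from None
    return model_from_dict(data)


def save_model(m: ProcessModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(m), fh, indent=2, ensure_ascii=False)
        fh.write("\n")


def validate_against_dictionary(
    m: ProcessModel, dictionary: Mapping[str, AttributeKind]
) -> None:
    """Check that condition kind indices agree with the attribute dictionary.

    Reserved lifecycle names are always kind=time; a named attribute whose
    dictionary kind disagrees with the condition's declared index is an error.
    """
    def check(name: str, declared: AttributeKind | None, where: str) -> None:
        if declared is None:
            return
        if name in (START_TIME, COMPLETE_TIME):
            actual = AttributeKind.TIME
        elif name in dictionary:
            actual = dictionary[name]
        else:
            return
        if actual != declared:
            raise ModelError(
                f"{where}: attribute {name!r} is kind={actual.label} "
                f"but the condition declares index {int(declared)} ({declared.label})"
            )

    for g in m.rules:
        for c in g.constraints:
            for cond in c.psi:
                where = f"rule {g.rule_id} ({c.cid})"
                for atom in cond.atoms:
                    if isinstance(atom, DiffAtom):
                        check(atom.time_attr_a, cond.i, where)
                        check(atom.time_attr_t, cond.j, where)
                    elif isinstance(atom, PairAtom):
                        check(atom.name_a, cond.i, where)
                        check(atom.name_t, cond.j, where)
                    else:
                        check(atom.name, cond.i if atom.side is not Side.TARGET else cond.j, where)
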