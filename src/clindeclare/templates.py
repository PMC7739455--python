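"""Declare template vocabulary and LTL-over-finite-traces semantics.

The template set is the standard Declare core, grouped into four families:

* Existence — existence, existence_n, absence, absence_n, exactly_n
* Choice — choice, exclusive_choice
* Relation — responded_existence, response, precedence, alternate_response,
  alternate_precedence, chain_response, chain_precedence
* Negative Relation — not_coexistence, not_succession, not_chain_succession

Counted templates use the convention: ``existence_n`` = at least n
occurrences, ``absence_n`` = at most n occurrences, ``exactly_n`` = exactly n.

``eval_ltl`` is a direct recursive evaluator of finite-trace LTL and serves
as the brute-force oracle against which the incremental conformance checker
is tested.  Finite-trace conventions: ``next`` is false at the last position
(and on the empty trace), ``weak_next`` is true there; ``weak_until`` holds
when the release condition never triggers.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence, Union

from .errors import ModelError
from .event_model import Trace

__all__ = [
    "TemplateKind",
    "TemplateFamily",
    "LTLFormula",
    "Atom",
    "Lit",
    "Not",
    "And",
    "Or",
    "Implies",
    "Next",
    "WeakNext",
    "Always",
    "Eventually",
    "Until",
    "WeakUntil",
    "template_to_ltl",
    "eval_ltl",
]


class TemplateFamily(Enum):
    EXISTENCE = "existence"
    CHOICE = "choice"
    RELATION = "relation"
    NEGATIVE_RELATION = "negative relation"


class TemplateKind(str, Enum):
    EXISTENCE = "existence"
    EXISTENCE_N = "existence_n"
    ABSENCE = "absence"
    ABSENCE_N = "absence_n"
    EXACTLY_N = "exactly_n"
    CHOICE = "choice"
    EXCLUSIVE_CHOICE = "exclusive_choice"
    RESPONDED_EXISTENCE = "responded_existence"
    RESPONSE = "response"
    PRECEDENCE = "precedence"
    ALTERNATE_RESPONSE = "alternate_response"
    ALTERNATE_PRECEDENCE = "alternate_precedence"
    CHAIN_RESPONSE = "chain_response"
    CHAIN_PRECEDENCE = "chain_precedence"
    NOT_COEXISTENCE = "not_coexistence"
    NOT_SUCCESSION = "not_succession"
    NOT_CHAIN_SUCCESSION = "not_chain_succession"

    @property
    def family(self) -> TemplateFamily:
        return _FAMILY[self]

    @property
    def is_binary(self) -> bool:
        """Binary templates relate a source and a target activity."""
        return self.family in (TemplateFamily.RELATION, TemplateFamily.NEGATIVE_RELATION) or (
            self.family is TemplateFamily.CHOICE
        )

    @property
    def takes_count(self) -> bool:
        return self in (TemplateKind.EXISTENCE_N, TemplateKind.ABSENCE_N, TemplateKind.EXACTLY_N)


_FAMILY = {
    TemplateKind.EXISTENCE: TemplateFamily.EXISTENCE,
    TemplateKind.EXISTENCE_N: TemplateFamily.EXISTENCE,
    TemplateKind.ABSENCE: TemplateFamily.EXISTENCE,
    TemplateKind.ABSENCE_N: TemplateFamily.EXISTENCE,
    TemplateKind.EXACTLY_N: TemplateFamily.EXISTENCE,
    TemplateKind.CHOICE: TemplateFamily.CHOICE,
    TemplateKind.EXCLUSIVE_CHOICE: TemplateFamily.CHOICE,
    TemplateKind.RESPONDED_EXISTENCE: TemplateFamily.RELATION,
    TemplateKind.RESPONSE: TemplateFamily.RELATION,
    TemplateKind.PRECEDENCE: TemplateFamily.RELATION,
    TemplateKind.ALTERNATE_RESPONSE: TemplateFamily.RELATION,
    TemplateKind.ALTERNATE_PRECEDENCE: TemplateFamily.RELATION,
    TemplateKind.CHAIN_RESPONSE: TemplateFamily.RELATION,
    TemplateKind.CHAIN_PRECEDENCE: TemplateFamily.RELATION,
    TemplateKind.NOT_COEXISTENCE: TemplateFamily.NEGATIVE_RELATION,
    TemplateKind.NOT_SUCCESSION: TemplateFamily.NEGATIVE_RELATION,
    TemplateKind.NOT_CHAIN_SUCCESSION: TemplateFamily.NEGATIVE_RELATION,
}


# --------------------------------------------------------------------------
# formula tree


@dataclass(frozen=True)
class Atom:
    activity: str


@dataclass(frozen=True)
class Lit:
    value: bool


@dataclass(frozen=True)
class Not:
    sub: "LTLFormula"


@dataclass(frozen=True)
class And:
    left: "LTLFormula"
    right: "LTLFormula"


@dataclass(frozen=True)
class Or:
    left: "LTLFormula"
    right: "LTLFormula"


@dataclass(frozen=True)
class Implies:
    left: "LTLFormula"
    right: "LTLFormula"


@dataclass(frozen=True)
class Next:
    sub: "LTLFormula"


@dataclass(frozen=True)
class WeakNext:
    sub: "LTLFormula"


@dataclass(frozen=True)
class Always:
    sub: "LTLFormula"


@dataclass(frozen=True)
class Eventually:
    sub: "LTLFormula"


@dataclass(frozen=True)
class Until:
    left: "LTLFormula"
    right: "LTLFormula"


@dataclass(frozen=True)
class WeakUntil:
    left: "LTLFormula"
    right: "LTLFormula"


LTLFormula = Union[
    Atom, Lit, Not, And, Or, Implies, Next, WeakNext, Always, Eventually, Until, WeakUntil
]


def eval_ltl(formula: LTLFormula, trace: Trace | Sequence[str]) -> bool:
    """Evaluate a formula on a finite trace (a :class:`Trace` or activity list).

    Position-indexed recursion; the empty trace is handled uniformly as the
    empty suffix (universal operators hold, existential ones fail).
    """
    acts = trace.activities() if isinstance(trace, Trace) else list(trace)
    return _holds(formula, acts, 0)


def _holds(f: LTLFormula, acts: list[str], i: int) -> bool:
    n = len(acts)
    if isinstance(f, Atom):
        return i < n and acts[i] == f.activity
    if isinstance(f, Lit):
        return f.value
    if isinstance(f, Not):
        return not _holds(f.sub, acts, i)
    if isinstance(f, And):
        return _holds(f.left, acts, i) and _holds(f.right, acts, i)
    if isinstance(f, Or):
        return _holds(f.left, acts, i) or _holds(f.right, acts, i)
    if isinstance(f, Implies):
        return (not _holds(f.left, acts, i)) or _holds(f.right, acts, i)
    if isinstance(f, Next):
        return i + 1 < n and _holds(f.sub, acts, i + 1)
    if isinstance(f, WeakNext):
        return i + 1 >= n or _holds(f.sub, acts, i + 1)
    if isinstance(f, Always):
        return all(_holds(f.sub, acts, j) for j in range(i, n))
    if isinstance(f, Eventually):
        return any(_holds(f.sub, acts, j) for j in range(i, n))
    if isinstance(f, Until):
        for j in range(i, n):
            if _holds(f.right, acts, j):
                return True
            if not _holds(f.left, acts, j):
                return False
        return False
    if isinstance(f, WeakUntil):
        for j in range(i, n):
            if _holds(f.right, acts, j):
                return True
            if not _holds(f.left, acts, j):
                return False
        return True
    raise TypeError(f"not an LTL formula node: {f!r}")


# --------------------------------------------------------------------------
# template formulas


def _at_least(a: str, n: int) -> LTLFormula:
    f: LTLFormula = Lit(True)
    for _ in range(n):
        f = Eventually(And(Atom(a), Next(f))) if not isinstance(f, Lit) else Eventually(Atom(a))
    return f if n > 0 else Lit(True)


def template_to_ltl(
    kind: TemplateKind, a: str, t: str | None = None, n: int | None = None
) -> LTLFormula:
    """The standard finite-trace LTL formula of a Declare template.

    ``a`` is the source activity, ``t`` the target (required for binary and
    choice templates), ``n`` the count for counted existence templates.
    """
    if kind.is_binary and not t:
        raise ModelError(f"template {kind.value} requires a target activity")
    if kind.takes_count:
        if n is None or n < 0:
            raise ModelError(f"template {kind.value} requires a count n >= 0")
    A, T = Atom(a), (Atom(t) if t else Lit(False))

    if kind is TemplateKind.EXISTENCE:
        return Eventually(A)
    if kind is TemplateKind.ABSENCE:
        return Not(Eventually(A))
    if kind is TemplateKind.EXISTENCE_N:
        return _at_least(a, n)  # type: ignore[arg-type]
    if kind is TemplateKind.ABSENCE_N:
        return Not(_at_least(a, n + 1))  # type: ignore[operator]
    if kind is TemplateKind.EXACTLY_N:
        return And(_at_least(a, n), Not(_at_least(a, n + 1)))  # type: ignore[operator]
    if kind is TemplateKind.CHOICE:
        return Or(Eventually(A), Eventually(T))
    if kind is TemplateKind.EXCLUSIVE_CHOICE:
        return And(
            Or(Eventually(A), Eventually(T)), Not(And(Eventually(A), Eventually(T)))
        )
    if kind is TemplateKind.RESPONDED_EXISTENCE:
        return Implies(Eventually(A), Eventually(T))
    if kind is TemplateKind.RESPONSE:
        return Always(Implies(A, Eventually(T)))
    if kind is TemplateKind.PRECEDENCE:
        return WeakUntil(Not(T), A)
    if kind is TemplateKind.ALTERNATE_RESPONSE:
        return Always(Implies(A, Next(Until(Not(A), T))))
    if kind is TemplateKind.ALTERNATE_PRECEDENCE:
        return And(
            WeakUntil(Not(T), A),
            Always(Implies(T, WeakNext(WeakUntil(Not(T), A)))),
        )
    if kind is TemplateKind.CHAIN_RESPONSE:
        return Always(Implies(A, Next(T)))
    if kind is TemplateKind.CHAIN_PRECEDENCE:
        return And(Not(T), Always(Implies(Next(T), A)))
    if kind is TemplateKind.NOT_COEXISTENCE:
        return Not(And(Eventually(A), Eventually(T)))
    if kind is TemplateKind.NOT_SUCCESSION:
        return Always(Implies(A, Not(Eventually(T))))
    if kind is TemplateKind.NOT_CHAIN_SUCCESSION:
        return Always(Implies(A, Not(Next(T))))
    raise ModelError(f"unsupported template: {kind!r}")
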