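"""Seeded generator of stroke-treatment-like event logs with known ground truth.

The hospital cohort behind the packaged stroke rules is private, so this
module builds surrogate episodes: every case is one thrombolysis admission
with the activities and attributes the rules reference (admit, CT and blood
glucose testing, a vital-signs measurement with systolic/diastolic values,
optional heparin pre-treatment, thrombolysis with start and complete times,
drug dispensing with executor/proofreader nurses, discharge).

Violations are injected *constructively*: with the configured per-rule
probability the generator builds the specific pattern that breaks the rule
(omit the CT, draw the door-to-needle time from the violated band, put the
heparin dose inside the 24 h window, let one nurse both dispense and
proofread) and records what it did.  Because injection is constructive,
conformance checking must recover the ground truth exactly, case by case —
no rejection sampling, no statistical tolerance.

Timestamps are minute-granular; case start times are spaced one day apart
from a fixed epoch, so identical seeds give byte-identical XES output.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .event_model import (
    AttributeKind,
    ClinicalAttribute,
    Event,
    EventLog,
    Trace,
)

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "RULE_IDS"]

#: rule-group ids of the packaged stroke model the generator targets
RULE_IDS = ("1.1", "1.2", "2", "3", "4", "5")

_EPOCH = datetime(2019, 1, 7, 8, 0)
_NURSES = ("Alice", "Ben", "Carol", "Dana", "Ed", "Fay", "Gil", "Hana")
_STAFF = ("Pete", "Sue", "Mike", "Sara", "Sean", "Ellen", "John")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one generated cohort.

    ``p_rule1``..``p_rule5`` are independent per-case injection
    probabilities; rule 1 has two sub-rules (1.1 CT, 1.2 blood glucose) and
    ``p_rule1`` applies to each independently.  Door-to-needle times are
    drawn uniformly (whole minutes) from the fulfilled band when compliant
    and from the violated band otherwise; both bounds are inclusive.
    """

    n_cases: int = 100
    cohort: str = "rt-PA"
    p_rule1: float = 0.0
    p_rule2: float = 0.0
    p_rule3: float = 0.0
    p_rule4: float = 0.0
    p_rule5: float = 0.0
    dnt_fulfilled: tuple[int, int] = (10, 59)
    dnt_violated: tuple[int, int] = (61, 240)
    pre_test_delay: tuple[int, int] = (2, 9)      # minutes after admission
    heparin_present_rate: float = 0.25            # compliant cases carrying an old heparin dose
    seed: int = 0

    def __post_init__(self):
        for name in ("p_rule1", "p_rule2", "p_rule3", "p_rule4", "p_rule5"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("dnt_fulfilled", "dnt_violated", "pre_test_delay"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} bounds must be positive and ordered, got ({lo}, {hi})")
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")


@dataclass
class GroundTruth:
    """The injected outcome of every (case, rule) pair."""

    entries: dict[tuple[str, str], str] = field(default_factory=dict)

    def outcome(self, case_id: str, rule_id: str) -> str:
        return self.entries[(case_id, rule_id)]

    def counts(self, rule_id: str) -> dict[str, int]:
        out = {"violated": 0, "fulfilled": 0, "vacuous": 0}
        for (cid, rid), outcome in self.entries.items():
            if rid == rule_id:
                out[outcome] += 1
        return out

    def to_csv(self, path=None) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["case_id", "rule_id", "outcome"])
        for (cid, rid), outcome in self.entries.items():
            writer.writerow([cid, rid, outcome])
        text = buf.getvalue()
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _minutes(base: datetime, m: int | float) -> datetime:
    return base + timedelta(minutes=int(m))


class _CaseBuilder:
    def __init__(self, case_id: str, rng: np.random.Generator):
        self.case_id = case_id
        self.rng = rng
        self.events: list[Event] = []
        self._n = 0

    def add(
        self,
        activity: str,
        complete: datetime | None,
        start: datetime | None = None,
        attrs: dict[str, ClinicalAttribute] | None = None,
        actor: str | None = None,
    ) -> Event:
        self._n += 1
        attributes = dict(attrs or {})
        if actor is None:
            actor = str(self.rng.choice(_STAFF))
        attributes.setdefault(
            "executor", ClinicalAttribute("executor", AttributeKind.ACTION, actor)
        )
        e = Event(
            f"{self.case_id}-{self._n}",
            activity,
            start_time=start,
            complete_time=complete,
            attributes=attributes,
        )
        self.events.append(e)
        return e


def generate(cfg: GeneratorConfig) -> tuple[EventLog, GroundTruth]:
    """Generate ``(log, ground_truth)`` under the given study conditions.

    Identical configs (including the seed) give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    traces: list[Trace] = []
    width = max(3, len(str(max(cfg.n_cases, 1))))
    for k in range(cfg.n_cases):
        case_id = f"case_{k + 1:0{width}d}"
        t0 = _EPOCH + timedelta(days=k)
        b = _CaseBuilder(case_id, rng)
        flags = {rid: False for rid in RULE_IDS}
        flags["1.1"] = rng.random() < cfg.p_rule1
        flags["1.2"] = rng.random() < cfg.p_rule1
        flags["2"] = rng.random() < cfg.p_rule2
        flags["3"] = rng.random() < cfg.p_rule3
        flags["4"] = rng.random() < cfg.p_rule4
        flags["5"] = rng.random() < cfg.p_rule5

        # admission (admin); the DNT clock starts here
        b.add("admit", t0, actor=str(rng.choice(_STAFF)))

        lo, hi = cfg.pre_test_delay

        # rule 1.1 — CT before thrombolysis (omitted when injected)
        if not flags["1.1"]:
            b.add("CT examination", _minutes(t0, rng.integers(lo, hi + 1)))
        if rng.random() < 0.3:  # incidental MRI; does not stand in for the CT
            b.add("MRI examination", _minutes(t0, rng.integers(lo, hi + 1)))

        # rule 1.2 — blood glucose before thrombolysis
        if not flags["1.2"]:
            glucose = ClinicalAttribute(
                "blood glucose", AttributeKind.OBSERVATION, float(rng.integers(4, 12))
            )
            b.add(
                "blood glucose test",
                _minutes(t0, rng.integers(lo, hi + 1)),
                attrs={"blood glucose": glucose},
            )

        # rule 3 — vital signs with systolic/diastolic observation attributes
        if flags["3"]:
            mode = rng.integers(0, 3)  # 0 systolic high, 1 diastolic high, 2 both
            sys_bp = int(rng.integers(180, 231)) if mode != 1 else int(rng.integers(100, 180))
            dia_bp = int(rng.integers(100, 131)) if mode != 0 else int(rng.integers(60, 100))
        else:
            sys_bp = int(rng.integers(100, 180))
            dia_bp = int(rng.integers(60, 100))
        b.add(
            "vital_signs test",
            _minutes(t0, rng.integers(lo, hi + 1)),
            attrs={
                "systolic pressure": ClinicalAttribute(
                    "systolic pressure", AttributeKind.OBSERVATION, sys_bp
                ),
                "diastolic pressure": ClinicalAttribute(
                    "diastolic pressure", AttributeKind.OBSERVATION, dia_bp
                ),
            },
        )

        # rule 2 — thrombolysis; DNT = complete(thrombolysis) - complete(admit)
        band = cfg.dnt_violated if flags["2"] else cfg.dnt_fulfilled
        dnt = int(rng.integers(band[0], band[1] + 1))
        thromb_complete = _minutes(t0, dnt)
        thromb_start = _minutes(t0, max(1, dnt - int(rng.integers(10, 31))))

        # rule 4 — heparin dose relative to the thrombolysis start
        if flags["4"]:
            gap = int(rng.integers(30, 1381))       # within 24 h -> both branches fail
            truth.entries[(case_id, "4")] = "violated"
        elif rng.random() < cfg.heparin_present_rate:
            gap = int(rng.integers(1500, 4001))     # dose safely older than 24 h
            truth.entries[(case_id, "4")] = "fulfilled"
        else:
            gap = None                              # no heparin at all
            truth.entries[(case_id, "4")] = "vacuous"
        if gap is not None:
            hep_complete = thromb_start - timedelta(minutes=gap)
            b.add("heparin injection", hep_complete, start=hep_complete - timedelta(minutes=15))

        b.add("thrombolysis", thromb_complete, start=thromb_start, actor=str(rng.choice(_STAFF)))

        # rule 5 — drug dispensing double-checked by two nurses
        if flags["5"]:
            nurse = str(rng.choice(_NURSES))
            executor, proofreader = nurse, nurse
        else:
            pick = rng.choice(len(_NURSES), size=2, replace=False)
            executor, proofreader = _NURSES[pick[0]], _NURSES[pick[1]]
        b.add(
            "dispensing drugs",
            _minutes(thromb_complete, rng.integers(10, 61)),
            attrs={
                "executor": ClinicalAttribute("executor", AttributeKind.ACTION, executor),
                "proofreader": ClinicalAttribute("proofreader", AttributeKind.ACTION, proofreader),
            },
            actor=executor,
        )

        # antipyretic administration activates rule 3's precedence check
        b.add("antipyretic", _minutes(thromb_complete, rng.integers(30, 121)))

        if rng.random() < 0.7:
            b.add("statins drugs", _minutes(thromb_complete, rng.integers(120, 601)))
        b.add("discharge", _minutes(t0, rng.integers(3 * 1440, 10 * 1440)))

        for rid in ("1.1", "1.2", "2", "3", "5"):
            truth.entries[(case_id, rid)] = "violated" if flags[rid] else "fulfilled"

        traces.append(
            Trace(case_id, b.events, attributes={"cohort": cfg.cohort})
        )
    return EventLog(traces), truth
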