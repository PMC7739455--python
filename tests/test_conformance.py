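import itertools
import warnings
from datetime import datetime, timedelta

import pytest
from hypothesis import given, strategies as st

from clindeclare.conformance import (
    FailureSection,
    Status,
    check_log,
    check_rulegroup,
    check_trace,
)
from clindeclare.constraint_model import ConstraintTuple, RuleGroup, parse_condition
from clindeclare.event_model import (
    AttributeKind,
    ClinicalAttribute,
    Event,
    EventLog,
    Trace,
)
from clindeclare.templates import TemplateKind, eval_ltl, template_to_ltl

from .conftest import make_trace

T0 = datetime(2019, 1, 13, 10, 0)


def _ev(eid, activity, complete_min, start_min=None, **attrs):
    attributes = {}
    for name, value in attrs.items():
        key = name.replace("_", " ")
        kind = AttributeKind.OBSERVATION if isinstance(value, (int, float)) else AttributeKind.ACTION
        attributes[key] = ClinicalAttribute(key, kind, value)
    return Event(
        str(eid),
        activity,
        start_time=None if start_min is None else T0 + timedelta(minutes=start_min),
        complete_time=T0 + timedelta(minutes=complete_min),
        attributes=attributes,
    )


class TestDntWorkedExample:
    """The three demo cases against rule 2 (DNT < 60 min), by direct arithmetic:
    case 1 Δ=40 fulfilled, case 2 no thrombolysis (vacuous), case 3 Δ=72 violated."""

    def test_case1_fulfilled(self, demo_log, rules_by_id):
        res = check_trace(demo_log.traces[0], rules_by_id["2"].constraints[0])
        assert len(res.activations) == 1
        assert res.satisfied and not res.vacuous
        assert res.activations[0].target.activity == "admit"

    def test_case2_vacuous(self, demo_log, rules_by_id):
        res = check_trace(demo_log.traces[1], rules_by_id["2"].constraints[0])
        assert res.activations == []
        assert res.vacuous and res.satisfied

    def test_case3_violated_in_data_section(self, demo_log, rules_by_id):
        res = check_trace(demo_log.traces[2], rules_by_id["2"].constraints[0])
        assert len(res.violations) == 1
        rec = res.violations[0]
        assert rec.section is FailureSection.DATA_FLOW
        assert rec.event.activity == "thrombolysis"

    def test_log_level_counts(self, demo_log, stroke):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = check_log(demo_log, stroke)
        assert report.counts("2") == {"violated": 1, "fulfilled": 1, "vacuous": 1}


class TestSelfCorrelation:
    """Rule-5 pattern: existence with a self-referencing action condition."""

    def _constraint(self):
        return ConstraintTuple(
            TemplateKind.EXISTENCE,
            "dispensing drugs",
            psi=(parse_condition("[executor, proofreader, !=]", 6, 6),),
        )

    def test_same_nurse_violates_data_flow(self):
        trace = Trace("c", [_ev(1, "dispensing drugs", 5, executor="Mike", proofreader="Mike")])
        res = check_trace(trace, self._constraint())
        assert not res.satisfied
        assert res.violations[0].section is FailureSection.DATA_FLOW

    def test_distinct_nurses_fulfil(self):
        trace = Trace("c", [_ev(1, "dispensing drugs", 5, executor="Mike", proofreader="Sue")])
        assert check_trace(trace, self._constraint()).satisfied

    def test_missing_proofreader_annotated_not_raised(self):
        trace = Trace("c", [_ev(1, "dispensing drugs", 5, executor="Mike")])
        res = check_trace(trace, self._constraint())
        rec = res.violations[0]
        assert rec.section is FailureSection.DATA_FLOW
        assert any("missing attribute 'proofreader'" in n for n in rec.notes)

    def test_absent_activity_is_control_flow_failure(self):
        trace = make_trace(["admit", "discharge"])
        res = check_trace(trace, self._constraint())
        assert not res.satisfied and not res.vacuous and not res.control_flow_ok


class TestHeparinDisjunction:
    """Rule 4: not-coexistence OR precedence with the dose > 24 h before needle."""

    def _group(self, rules_by_id):
        return rules_by_id["4"]

    def test_no_heparin_satisfies_first_branch(self, rules_by_id):
        trace = Trace("c", [_ev(1, "admit", 0), _ev(2, "thrombolysis", 45, start_min=30)])
        gr = check_rulegroup(trace, self._group(rules_by_id))
        assert gr.satisfied
        assert gr.outcome == "vacuous"  # no heparin event activates either branch

    def test_old_dose_satisfies_second_branch(self, rules_by_id):
        # heparin completed 1500 min before the thrombolysis start
        trace = Trace(
            "c",
            [
                _ev(1, "heparin injection", -1500),
                _ev(2, "admit", 0),
                _ev(3, "thrombolysis", 45, start_min=0),
            ],
        )
        gr = check_rulegroup(trace, self._group(rules_by_id))
        assert gr.satisfied and gr.outcome == "fulfilled"
        assert gr.best.constraint.template is TemplateKind.PRECEDENCE

    def test_recent_dose_violates_both_branches(self, rules_by_id):
        # heparin completed only 240 min before the start: coexists AND too recent
        trace = Trace(
            "c",
            [
                _ev(1, "heparin injection", -240),
                _ev(2, "admit", 0),
                _ev(3, "thrombolysis", 45, start_min=0),
            ],
        )
        gr = check_rulegroup(trace, self._group(rules_by_id))
        assert not gr.satisfied and gr.outcome == "violated"
        assert all(not r.satisfied for r in gr.branch_results)


class TestBloodPressureGate:
    """Rule 3: the activation-side conjunction qualifies the vital-signs source."""

    def test_high_systolic_is_data_flow_violation(self, rules_by_id):
        trace = Trace(
            "c",
            [
                _ev(1, "vital_signs test", 0, systolic_pressure=190, diastolic_pressure=80),
                _ev(2, "antipyretic", 30),
            ],
        )
        res = check_trace(trace, rules_by_id["3"].constraints[0])
        assert not res.satisfied
        assert res.violations[0].section is FailureSection.DATA_FLOW

    def test_no_vital_signs_at_all_is_control_flow(self, rules_by_id):
        trace = Trace("c", [_ev(1, "antipyretic", 30)])
        res = check_trace(trace, rules_by_id["3"].constraints[0])
        assert res.violations[0].section is FailureSection.CONTROL_FLOW

    def test_later_compliant_measurement_qualifies(self, rules_by_id):
        trace = Trace(
            "c",
            [
                _ev(1, "vital_signs test", 0, systolic_pressure=190, diastolic_pressure=80),
                _ev(2, "vital_signs test", 5, systolic_pressure=150, diastolic_pressure=80),
                _ev(3, "antipyretic", 30),
            ],
        )
        assert check_trace(trace, rules_by_id["3"].constraints[0]).satisfied


class TestLogLevel:
    def test_empty_log_all_zero(self, stroke):
        report = check_log(EventLog([]), stroke)
        assert report.n_traces == 0
        assert report.outcomes == []
        assert report.violated_case_ids == []

    def test_unknown_model_activity_warns_but_checks(self, stroke, demo_log):
        with pytest.warns(UserWarning, match="never occur in the log"):
            report = check_log(demo_log, stroke)
        assert report.counts("4") == {"violated": 0, "fulfilled": 0, "vacuous": 3}

    def test_optional_rules_do_not_flip_cases(self, demo_log):
        from clindeclare.constraint_model import ProcessModel

        c = ConstraintTuple(
            TemplateKind.EXISTENCE, "dispensing drugs", mandatory=False, cid="opt"
        )
        m = ProcessModel(
            "opt", frozenset({"dispensing drugs"}), (RuleGroup("opt", "", (c,), mandatory=False),)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = check_log(demo_log, m)
        assert report.counts("opt")["violated"] == 3
        assert report.violated_case_ids == []  # optional rules never hit the headline

    def test_table_columns_sum_to_cohort_size(self, demo_log, stroke):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = check_log(demo_log, stroke)
        for rid in report.rule_ids:
            n = report.counts(rid)
            assert n["violated"] + n["fulfilled"] + n["vacuous"] == 3


# --------------------------------------------------------------------------
# properties

_TEMPLATES = [k for k in TemplateKind if not k.takes_count]
_tr = st.lists(st.sampled_from("ATX"), max_size=8)


def _constraint_for(kind):
    return ConstraintTuple(kind, "A", "T" if kind.is_binary else None)


class TestCheckerProperties:
    @given(_tr, st.sampled_from(_TEMPLATES))
    def test_activation_partition(self, acts, kind):
        res = check_trace(make_trace(acts), _constraint_for(kind))
        assert len(res.activations) == len(res.fulfillments) + len(res.violations)
        assert all(r.status is not Status.PENDING for r in res.activations)

    @given(_tr, st.sampled_from(_TEMPLATES))
    def test_agrees_with_ltl_oracle(self, acts, kind):
        c = _constraint_for(kind)
        f = template_to_ltl(kind, c.a, c.t)
        assert check_trace(make_trace(acts), c).satisfied == eval_ltl(f, acts)

    @given(_tr)
    def test_determinism(self, acts):
        c = _constraint_for(TemplateKind.RESPONSE)
        r1 = check_trace(make_trace(acts), c)
        r2 = check_trace(make_trace(acts), c)
        assert [a.status for a in r1.activations] == [a.status for a in r2.activations]
        assert r1.satisfied == r2.satisfied

    @given(_tr)
    def test_appending_target_never_hurts_response(self, acts):
        """Monotone fulfillment: a trailing qualifying target cannot increase
        the violation count of a response constraint."""
        c = _constraint_for(TemplateKind.RESPONSE)
        before = len(check_trace(make_trace(acts), c).violations)
        after = len(check_trace(make_trace(list(acts) + ["T"]), c).violations)
        assert after <= before

    @given(_tr)
    def test_not_coexistence_symmetric_satisfaction(self, acts):
        a = check_trace(make_trace(acts), ConstraintTuple(TemplateKind.NOT_COEXISTENCE, "A", "T"))
        b = check_trace(make_trace(acts), ConstraintTuple(TemplateKind.NOT_COEXISTENCE, "T", "A"))
        assert a.satisfied == b.satisfied
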