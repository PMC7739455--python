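import pytest
from hypothesis import given, strategies as st

from clindeclare.constraint_model import (
    ConditionRole,
    ConstantAtom,
    ConstraintTuple,
    DataCondition,
    DiffAtom,
    Op,
    PairAtom,
    ProcessModel,
    RuleGroup,
    build_matrix,
    format_condition,
    load_model,
    model_from_dict,
    model_to_dict,
    parse_condition,
    save_model,
    validate_against_dictionary,
)
from clindeclare.errors import ConditionParseError, ModelError
from clindeclare.event_model import AttributeKind
from clindeclare.templates import TemplateKind


class TestConditionParsing:
    def test_timestamp_difference_atom(self):
        """DNT condition: thrombolysis completes within 60 min of admission."""
        cond = parse_condition("[complete time, complete time, 60, <]", i=1, j=1)
        assert cond.role is ConditionRole.CORRELATION
        (atom,) = cond.atoms
        assert atom == DiffAtom("complete time", "complete time", 60.0, Op.LT, "60")

    def test_pair_atom_with_spaced_inequality(self):
        """Double-check condition, operator spelled '! =' as printed."""
        cond = parse_condition("[executor, proofreader, ! =]", i=6, j=6)
        (atom,) = cond.atoms
        assert atom == PairAtom("executor", "proofreader", Op.NE)

    def test_arithmetic_threshold(self):
        cond = parse_condition("[complete time, start time, 24*60, >]", i=1, j=1)
        (atom,) = cond.atoms
        assert atom.threshold_minutes == 1440.0
        assert atom.threshold_text == "24*60"  # printed form preserved

    def test_conjunction_of_constant_atoms(self):
        cond = parse_condition(
            "[systolic pressure, 180, <]&[diastolic pressure, 100, <]", i=3
        )
        assert cond.role is ConditionRole.ACTIVATION
        assert [a.name for a in cond.atoms] == ["systolic pressure", "diastolic pressure"]
        assert [a.constant for a in cond.atoms] == [180, 100]

    def test_empty_text_is_null_condition(self):
        cond = parse_condition("", i=1)
        assert cond.is_null

    @pytest.mark.parametrize(
        "text,err",
        [
            ("[a, 5, ?]", ConditionParseError),
            ("[a, b]", ConditionParseError),
            ("[a, b, c, d, =]", ConditionParseError),
            ("junk", ConditionParseError),
        ],
    )
    def test_malformed_text_rejected(self, text, err):
        with pytest.raises(err):
            parse_condition(text, i=1, j=1)

    def test_diff_atom_requires_time_kind_indices(self):
        with pytest.raises(ModelError, match=r"\(1,1\)"):
            parse_condition("[complete time, complete time, 60, <]", i=3, j=3)

    def test_condition_without_indices_rejected(self):
        with pytest.raises(ModelError, match="kind index"):
            parse_condition("[a, 5, <]")


class TestConditionFormatting:
    TABLE_STRINGS = [
        ("[complete time, complete time, 60, <]", 1, 1),
        ("[systolic pressure, 180, <]&[diastolic pressure, 100, <]", 3, None),
        ("[complete time, start time, 24*60, >]", 1, 1),
        ("[executor, proofreader, !=]", 6, 6),
    ]

    @pytest.mark.parametrize("text,i,j", TABLE_STRINGS)
    def test_format_of_parse_is_identity_on_canonical_strings(self, text, i, j):
        assert format_condition(parse_condition(text, i, j)) == text

    @pytest.mark.parametrize("text,i,j", TABLE_STRINGS)
    def test_parse_of_format_is_structural_identity(self, text, i, j):
        cond = parse_condition(text, i, j)
        assert parse_condition(format_condition(cond), i, j) == cond


class TestConstraintTuples:
    def test_binary_template_needs_target(self):
        with pytest.raises(ModelError, match="requires a target"):
            ConstraintTuple(TemplateKind.PRECEDENCE, "admit")

    def test_unary_cannot_carry_target_condition(self):
        cond = DataCondition(
            (ConstantAtom("x", Op.LT, 5),), ConditionRole.TARGET, j=AttributeKind.OBSERVATION
        )
        with pytest.raises(ModelError, match="target condition"):
            ConstraintTuple(TemplateKind.EXISTENCE, "a", psi=(cond,))

    def test_unary_self_correlation_allowed(self):
        cond = parse_condition("[executor, proofreader, !=]", i=6, j=6)
        c = ConstraintTuple(TemplateKind.EXISTENCE, "dispensing drugs", psi=(cond,))
        assert c.psi[0].role is ConditionRole.CORRELATION


class TestMatrix:
    def test_single_cell_for_dnt_constraint(self, rules_by_id):
        c = rules_by_id["2"].constraints[0]
        m = build_matrix(c)
        assert m.cell(AttributeKind.TIME, AttributeKind.TIME) is not None
        assert len(m.flatten()) == 1

    def test_empty_psi_gives_all_null_matrix(self):
        c = ConstraintTuple(TemplateKind.RESPONSE, "a", "b")
        assert build_matrix(c).flatten() == []

    def test_activation_row_holds_conjunction(self, rules_by_id):
        c = rules_by_id["3"].constraints[0]
        m = build_matrix(c)
        cell = m.cell(AttributeKind.OBSERVATION, None)
        assert cell is not None and len(cell.atoms) == 2

    def test_same_cell_conditions_merge_by_conjunction(self):
        c1 = parse_condition("[x, 1, <]", i=3)
        c2 = parse_condition("[y, 2, >]", i=3)
        c = ConstraintTuple(TemplateKind.RESPONSE, "a", "b", psi=(c1, c2))
        m = build_matrix(c)
        assert len(m.flatten()) == 1
        assert len(m.cell(AttributeKind.OBSERVATION, None).atoms) == 2

    def test_flatten_covers_psi_exactly(self, stroke):
        for c in stroke.constraints():
            flat = build_matrix(c).flatten()
            flat_atoms = [a for cond in flat for a in cond.atoms]
            psi_atoms = [a for cond in c.psi for a in cond.atoms]
            assert sorted(flat_atoms, key=repr) == sorted(psi_atoms, key=repr)


class TestModelFiles:
    def test_packaged_stroke_model_shape(self, stroke):
        assert len(stroke.rules) == 6  # rule 1 splits into 1.1 and 1.2
        assert len(stroke.constraints()) == 7
        assert [g.rule_id for g in stroke.rules] == ["1.1", "1.2", "2", "3", "4", "5"]
        assert [g.label for g in stroke.rules] == ["1", "1", "2", "3", "4", "5"]

    def test_roundtrip_of_packaged_model(self, stroke, tmp_path):
        path = tmp_path / "m.json"
        save_model(stroke, path)
        assert load_model(path) == stroke

    def test_empty_rules_model_is_valid(self):
        m = model_from_dict({"name": "empty", "alphabet": ["a"], "rules": []})
        assert m.rules == ()

    def test_unknown_activity_rejected(self):
        with pytest.raises(ModelError, match="not in the model alphabet"):
            model_from_dict(
                {
                    "name": "bad",
                    "alphabet": ["a"],
                    "rules": [
                        {"description": "", "any_of": [{"template": "existence", "A": "ghost"}]}
                    ],
                }
            )

    def test_unknown_template_names_path(self):
        with pytest.raises(ModelError, match=r"rules\[0\].any_of\[0\]"):
            model_from_dict(
                {
                    "name": "bad",
                    "alphabet": ["a"],
                    "rules": [{"description": "", "any_of": [{"template": "wat", "A": "a"}]}],
                }
            )

    def test_kind_mismatch_against_dictionary(self, stroke):
        with pytest.raises(ModelError, match="kind=admin"):
            validate_against_dictionary(stroke, {"systolic pressure": AttributeKind.ADMIN})

    @given(
        specs=st.lists(
            st.tuples(
                st.sampled_from(
                    [TemplateKind.RESPONSE, TemplateKind.PRECEDENCE, TemplateKind.EXISTENCE]
                ),
                st.sampled_from(["a", "b"]),
                st.sampled_from(["c", "d"]),
                st.booleans(),
            ),
            max_size=5,
        )
    )
    def test_roundtrip_on_randomized_models(self, specs, tmp_path):
        rules = []
        for k, (kind, a, t, mandatory) in enumerate(specs):
            psi = ()
            if kind is not TemplateKind.EXISTENCE:
                psi = (parse_condition("[complete time, complete time, 30, <]", 1, 1),)
            rules.append(
                RuleGroup(
                    str(k + 1),
                    f"rule {k}",
                    (
                        ConstraintTuple(
                            kind,
                            a,
                            t if kind is not TemplateKind.EXISTENCE else None,
                            psi,
                            mandatory,
                            cid=str(k + 1),
                        ),
                    ),
                    mandatory,
                )
            )
        m = ProcessModel("rand", frozenset("abcd"), tuple(rules))
        assert model_from_dict(model_to_dict(m)) == m
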