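"""Rule composition, canonical rendering, syntax validation, evaluation."""

import pytest
from rdflib import Graph, RDF

from dxcriteria import (
    compose_rule,
    evaluate_rule,
    parse_hqmf_document,
    populate_dcdo,
    render_rule,
    validate_rule,
)
from dxcriteria.criteria_text import parse_criterion_text, render_hqmf
from dxcriteria.errors import CompositionError, UsageError
from dxcriteria.swrl_engine import (
    SWRL,
    FactSet,
    SwrlAtom,
    SwrlRule,
    ind,
    lit,
    map_operator,
    serialize_rules_owl,
    var,
)
from tests.conftest import brute_force_inferences, random_facts_for, random_numeric_spec

TARGET_RULE = (
    "Patient(?x), LDL-c(?y), has_result_comparison(?x, ?y), has_value(?y, ?z), "
    "int(?z), has_unit(?y, mg/dL), lessThan(?z, 100) -> has_evidence(?x, ev1)"
)


@pytest.fixture()
def worked_example_rule(dcuo, lab_criterion):
    dcdo, _ = populate_dcdo(dcuo, [lab_criterion])
    return compose_rule(lab_criterion, dcdo, 1)


def _rule_for(text: str, dcuo, index: int = 1):
    (criterion,) = parse_hqmf_document(render_hqmf(parse_criterion_text(text)))
    dcdo, _ = populate_dcdo(dcuo, [criterion])
    return compose_rule(criterion, dcdo, index)


class TestCompose:
    def test_worked_example_rule_string(self, worked_example_rule):
        assert render_rule(worked_example_rule) == TARGET_RULE

    def test_builtin_threshold_is_the_criterion_value(self, worked_example_rule):
        (builtin,) = [a for a in worked_example_rule.body if a.atom_kind == "builtin"]
        assert builtin.predicate == "lessThan"
        assert builtin.arguments[1] == ("lit", 100.0)

    def test_inclusive_low_bound_without_unit(self, dcuo):
        rule = _rule_for("Laboratory Test, Result: INR (result > = 2)", dcuo)
        kinds = [a.atom_kind for a in rule.body]
        assert "builtin" in kinds
        (builtin,) = [a for a in rule.body if a.atom_kind == "builtin"]
        assert builtin.predicate == "greaterThanOrEqual"
        assert not any(a.predicate == "has_unit" for a in rule.body)

    def test_nominal_rule_has_no_builtin(self, dcuo):
        rule = _rule_for(
            "Laboratory Test, Result: Hepatitis A Antigen Test (result: 'Seropositive')",
            dcuo,
        )
        kinds = {a.atom_kind for a in rule.body}
        assert "builtin" not in kinds and "data_range" not in kinds
        assert SwrlAtom("individual_property", "has_result",
                        (var("y"), ind("Seropositive"))) in rule.body
        # nominal criteria link patient and observation through has_result
        assert SwrlAtom("individual_property", "has_result",
                        (var("x"), var("y"))) in rule.body

    def test_head_evidence_individual_indexed(self, dcuo, lab_criterion):
        dcdo, _ = populate_dcdo(dcuo, [lab_criterion])
        rule = compose_rule(lab_criterion, dcdo, 7)
        assert render_rule(rule).endswith("-> has_evidence(?x, ev7)")
        assert "ev7" in dcdo.individuals

    def test_missing_value_set_class_raises(self, dcuo, lab_criterion):
        with pytest.raises(CompositionError):
            compose_rule(lab_criterion, dcuo.copy(), 1)

    def test_non_integral_threshold_uses_decimal_range(self, dcuo):
        rule = _rule_for("Laboratory Test, Result: HbA1c (result < 6.5 %)", dcuo)
        (rng_atom,) = [a for a in rule.body if a.atom_kind == "data_range"]
        assert rng_atom.predicate == "decimal"


class TestMapOperator:
    @pytest.mark.parametrize(("bound", "inclusive", "expected"), [
        ("high", False, "lessThan"),
        ("high", True, "lessThanOrEqual"),
        ("low", False, "greaterThan"),
        ("low", True, "greaterThanOrEqual"),
        ("both", True, "equal"),
    ])
    def test_mapping(self, bound, inclusive, expected):
        assert map_operator(bound, inclusive) == expected

    def test_no_builtin_for_absent_bound(self):
        with pytest.raises(UsageError):
            map_operator("none", True)


class TestRender:
    def test_empty_body_still_renders(self):
        rule = SwrlRule("r", [], [SwrlAtom("individual_property", "has_evidence",
                                           (var("x"), ind("ev1")))])
        assert render_rule(rule) == " -> has_evidence(?x, ev1)"

    def test_injective_on_corpus(self, corpus_criteria, corpus_dcdo):
        rules = [compose_rule(c, corpus_dcdo, i + 1)
                 for i, c in enumerate(corpus_criteria)]
        rendered = [render_rule(r) for r in rules]
        assert len(set(rendered)) == len(rendered)

    def test_byte_stable(self, worked_example_rule):
        assert render_rule(worked_example_rule) == render_rule(worked_example_rule)


class TestValidate:
    def test_worked_example_valid(self, worked_example_rule):
        report = validate_rule(worked_example_rule)
        assert report.valid and not report.violations

    def test_bracketed_unit_fails_illegal_char(self, dcuo):
        rule = _rule_for(
            "Laboratory Test, Result: HIV Viral Load (result < 200 copies/mL)", dcuo
        )
        report = validate_rule(rule)
        assert not report.valid
        assert [(v.code, v.offending) for v in report.violations] == [
            ("ILLEGAL_CHAR", "[copies]/mL")
        ]

    def test_unsafe_head_variable(self, worked_example_rule):
        bad = SwrlRule("r", worked_example_rule.body,
                       [SwrlAtom("individual_property", "has_evidence",
                                 (var("w"), ind("ev1")))])
        report = validate_rule(bad)
        assert [v.code for v in report.violations] == ["UNSAFE_HEAD_VAR"]

    def test_malformed_atom_arity(self):
        rule = SwrlRule("r", [SwrlAtom("class", "Patient", (var("x"), var("y")))],
                        [SwrlAtom("individual_property", "p", (var("x"), ind("i")))])
        assert "MALFORMED_ATOM" in [v.code for v in validate_rule(rule).violations]

    def test_unknown_builtin(self):
        rule = SwrlRule("r", [SwrlAtom("builtin", "stringConcat",
                                       (var("z"), lit(1)))],
                        [SwrlAtom("individual_property", "p",
                                  (ind("a"), ind("b")))])
        assert "UNKNOWN_BUILTIN" in [v.code for v in validate_rule(rule).violations]

    def test_empty_head(self):
        rule = SwrlRule("r", [SwrlAtom("class", "Patient", (var("x"),))], [])
        assert [v.code for v in validate_rule(rule).violations] == ["EMPTY_HEAD"]

    def test_sound_on_bracket_free_corpus(self, corpus_criteria, corpus_dcdo):
        """Every rule composed from a bracket-free criterion validates."""
        for i, criterion in enumerate(corpus_criteria, start=1):
            cmp = criterion.comparison
            if cmp is not None and cmp.unit and "[" in cmp.unit:
                continue
            rule = compose_rule(criterion, corpus_dcdo, i)
            assert validate_rule(rule).valid, criterion.title


class TestEvaluate:
    @pytest.fixture()
    def worked_facts(self):
        facts = FactSet()
        facts.add_class("p1", "Patient")
        facts.add_class("o1", "LDL-c")
        facts.add_property("p1", "has_result_comparison", "o1")
        facts.add_data("o1", "has_value", 90, unit="mg/dL")
        return facts

    def test_satisfied_body_infers_evidence(self, worked_example_rule, worked_facts):
        assert evaluate_rule(worked_example_rule, worked_facts) == {
            ("p1", "has_evidence", "ev1")
        }

    def test_boundary_value_excluded_by_strict_less_than(
        self, worked_example_rule, worked_facts
    ):
        worked_facts.data_assertions = {("o1", "has_value", 100.0)}
        worked_facts.add_property("o1", "has_unit", "mg/dL")
        assert evaluate_rule(worked_example_rule, worked_facts) == set()

    def test_unit_mismatch_blocks_inference(self, worked_example_rule):
        facts = FactSet()
        facts.add_class("p1", "Patient")
        facts.add_class("o1", "LDL-c")
        facts.add_property("p1", "has_result_comparison", "o1")
        facts.add_data("o1", "has_value", 90, unit="mmol/L")
        assert evaluate_rule(worked_example_rule, facts) == set()

    def test_invalid_rule_rejected(self):
        rule = SwrlRule("r", [], [])
        with pytest.raises(UsageError):
            evaluate_rule(rule, FactSet())

    @pytest.mark.parametrize("case_seed", range(200))
    def test_agrees_with_brute_force_oracle(self, dcuo, case_seed):
        """Single-rule forward chaining matches an independent direct
        evaluation of 'value OP threshold and unit matches and patient
        linked' over random criteria and random fact sets."""
        spec = random_numeric_spec(case_seed)
        (criterion,) = parse_hqmf_document(render_hqmf(spec))
        dcdo, _ = populate_dcdo(dcuo, [criterion])
        rule = compose_rule(criterion, dcdo, 1)
        if not validate_rule(rule).valid:  # bracketed UCUM units
            return
        facts = random_facts_for(spec, seed=case_seed + 10_000)
        assert evaluate_rule(rule, facts) == brute_force_inferences(
            spec, facts, "ev1"
        )


class TestEndToEnd:
    def test_corpus_outcome(self, corpus_criteria, corpus_dcdo):
        rules = [compose_rule(c, corpus_dcdo, i + 1)
                 for i, c in enumerate(corpus_criteria)]
        reports = [validate_rule(r) for r in rules]
        assert len(rules) == 15
        assert sum(r.valid for r in reports) == 14
        (invalid,) = [rule for rule, rep in zip(rules, reports) if not rep.valid]
        assert "HIV Viral Load" in invalid.source_criterion

    def test_rules_embed_in_owl(self, corpus_criteria, corpus_dcdo):
        rules = [compose_rule(c, corpus_dcdo, i + 1)
                 for i, c in enumerate(corpus_criteria)]
        text = serialize_rules_owl(rules, corpus_dcdo, "rdfxml")
        g = Graph()
        g.parse(data=text, format="xml")
        imps = list(g.subjects(RDF.type, SWRL.Imp))
        assert len(imps) == 15
        for imp in imps:
            assert g.value(imp, SWRL.body) is not None
            assert g.value(imp, SWRL.head) is not None
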