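"""Shared fixtures: ontologies, criterion corpora, and fact-set generation."""

from __future__ import annotations

import random

import pytest

from dxcriteria import (
    build_dcuo,
    parse_hqmf_document,
    populate_dcdo,
)
from dxcriteria.criteria_text import (
    CriterionSpec,
    generate_random_criteria,
    read_criteria_file,
    render_hqmf,
)
from dxcriteria.examples import example_criteria_text, example_lab_document
from dxcriteria.ontology_core import sanitize_name
from dxcriteria.swrl_engine import FactSet


@pytest.fixture(scope="session")
def dcuo():
    return build_dcuo()


@pytest.fixture(scope="session")
def lab_document() -> str:
    return example_lab_document()


@pytest.fixture(scope="session")
def lab_criterion(lab_document):
    """The parsed LDL-c worked-example criterion."""
    return parse_hqmf_document(lab_document)[0]


@pytest.fixture(scope="session")
def corpus_specs() -> list[CriterionSpec]:
    """The 15-criterion laboratory corpus in textual form."""
    return read_criteria_file(example_criteria_text())


@pytest.fixture(scope="session")
def corpus_criteria(corpus_specs):
    """The corpus rendered to HQMF and parsed back, in order."""
    return [parse_hqmf_document(render_hqmf(s))[0] for s in corpus_specs]


@pytest.fixture(scope="session")
def corpus_dcdo(dcuo, corpus_criteria):
    dcdo, _ = populate_dcdo(dcuo, corpus_criteria)
    return dcdo


def random_numeric_spec(seed: int) -> CriterionSpec:
    """One random numeric-comparison criterion, deterministic in *seed*."""
    rng = random.Random(seed)
    while True:
        spec = generate_random_criteria(1, rng.randrange(2**31))[0]
        if spec.result_kind == "comparison":
            return spec


def random_facts_for(spec: CriterionSpec, seed: int) -> FactSet:
    """A random toy fact set exercising a numeric criterion.

    Includes boundary values (observation value equal to the threshold),
    wrong units, wrong classes and unlinked observations so that every
    branch of the rule body is stressed.
    """
    rng = random.Random(seed)
    facts = FactSet()
    vs_class = str(sanitize_name(spec.value_set_name))
    right_unit = spec.unit
    patients = [f"p{i}" for i in range(rng.randint(1, 3))]
    for p in patients:
        facts.add_class(p, "Patient")
    for j in range(rng.randint(1, 5)):
        obs = f"o{j}"
        facts.add_class(obs, vs_class if rng.random() < 0.8 else "OtherTest")
        if rng.random() < 0.85:
            facts.add_property(rng.choice(patients), "has_result_comparison", obs)
        value = rng.choice([
            spec.value,                       # boundary: value == threshold
            spec.value - 1, spec.value + 1,
            float(rng.randint(0, 600)),
            spec.value + 0.5,                 # non-integral vs int(?z)
        ])
        unit_roll = rng.random()
        if right_unit is None or unit_roll < 0.6:
            unit = right_unit
        elif unit_roll < 0.8:
            unit = "furlong"                  # unit mismatch
        else:
            unit = None                       # unit absent
        facts.add_data(obs, "has_value", value, unit=unit)
    return facts


def brute_force_inferences(
    spec: CriterionSpec, facts: FactSet, evidence: str
) -> set[tuple[str, str, str]]:
    """Direct predicate evaluation of a numeric criterion over a fact set.

    Independent of the rule engine: enumerates (patient, observation)
    pairs and checks class membership, the value comparison, the integral
    data-range restriction, and the exact unit-individual match.
    """
    import operator

    ops = {"lt": operator.lt, "le": operator.le, "gt": operator.gt,
           "ge": operator.ge, "eq": operator.eq}
    op = ops[spec.operator]
    threshold = float(spec.value)
    int_range = float(threshold).is_integer()
    vs_class = str(sanitize_name(spec.value_set_name))
    unit_id = str(sanitize_name(spec.unit)) if spec.unit else None

    patients = {i for i, c in facts.class_assertions if c == "Patient"}
    members = {i for i, c in facts.class_assertions if c == vs_class}
    inferred = set()
    for p, prop, o in facts.property_assertions:
        if prop != "has_result_comparison" or p not in patients or o not in members:
            continue
        for s, dprop, v in facts.data_assertions:
            if s != o or dprop != "has_value":
                continue
            if int_range and not float(v).is_integer():
                continue
            if unit_id is not None and (o, "has_unit", unit_id) not in facts.property_assertions:
                continue
            if op(v, threshold):
                inferred.add((p, "has_evidence", evidence))
    return inferred
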