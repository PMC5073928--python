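"""Compose, render, validate and evaluate SWRL rules.

A rule has a body (antecedent) and a head (consequent), each an ordered
conjunction of atoms.  Seven atom kinds are modeled: class, individual
property, data valued property, built-in, data range, same individual and
different individual (the last two are representable but never emitted by
the composer).

A numeric laboratory criterion such as ``LDL-c (result < 100 mg/dL)``
composes to::

    Patient(?x), LDL-c(?y), has_result_comparison(?x, ?y),
    has_value(?y, ?z), int(?z), has_unit(?y, mg/dL),
    lessThan(?z, 100) -> has_evidence(?x, ev1)

Validation checks the SWRL safety condition and identifier legality; the
characteristic failure is a unit individual such as ``[copies]/mL`` whose
square brackets are illegal in SWRL identifiers.  :func:`evaluate_rule`
runs single-rule forward chaining over a toy fact set and serves as the
semantic oracle for the composed rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Sequence, Union

from rdflib import BNode, Graph, Literal as RdfLiteral, Namespace, RDF, URIRef
from rdflib.namespace import XSD

from dxcriteria.errors import CompositionError, UsageError
from dxcriteria.hqmf_io import ComparisonSpec, HqmfCriterion
from dxcriteria.dcdo_populator import (
    HAS_RESULT,
    HAS_RESULT_COMPARISON,
    evidence_individual,
)
from dxcriteria.ontology_core import (
    PATIENT,
    Identifier,
    Ontology,
    ontology_to_graph,
    sanitize_name,
)
from dxcriteria.ontology_core import NAMESPACES, ENTITY_NS
from urllib.parse import quote

AtomKind = Literal[
    "class",
    "individual_property",
    "data_valued_property",
    "builtin",
    "data_range",
    "same_individual",
    "different_individual",
]

#: Argument of an atom: a variable, a named individual, or a literal.
Var = tuple[Literal["var"], str]
Ind = tuple[Literal["ind"], str]
Lit = tuple[Literal["lit"], float]
Argument = Union[Var, Ind, Lit]


def var(name: str) -> Var:
    return ("var", name)


def ind(name: str) -> Ind:
    return ("ind", str(name))


def lit(value: float) -> Lit:
    return ("lit", float(value))


SUPPORTED_BUILTINS = frozenset({
    "lessThan", "lessThanOrEqual", "greaterThan", "greaterThanOrEqual",
    "equal", "notEqual",
})

_BUILTIN_PYTHON = {
    "lessThan": lambda a, b: a < b,
    "lessThanOrEqual": lambda a, b: a <= b,
    "greaterThan": lambda a, b: a > b,
    "greaterThanOrEqual": lambda a, b: a >= b,
    "equal": lambda a, b: a == b,
    "notEqual": lambda a, b: a != b,
}

_UNARY_KINDS = {"class", "data_range"}


@dataclass(frozen=True)
class SwrlAtom:
    atom_kind: AtomKind
    predicate: str
    arguments: tuple[Argument, ...]

    def variables(self) -> set[str]:
        return {a[1] for a in self.arguments if a[0] == "var"}


@dataclass
class SwrlRule:
    rule_id: str
    body: list[SwrlAtom]
    head: list[SwrlAtom]
    source_criterion: str = ""


@dataclass(frozen=True)
class Violation:
    code: Literal[
        "ILLEGAL_CHAR", "UNSAFE_HEAD_VAR", "MALFORMED_ATOM",
        "UNKNOWN_BUILTIN", "EMPTY_HEAD",
    ]
    message: str
    offending: str


@dataclass
class ValidationReport:
    valid: bool
    violations: list[Violation] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "violations": [
                {"code": v.code, "message": v.message, "offending": v.offending}
                for v in self.violations
            ],
        }


# ---------------------------------------------------------------------------
# Composition

def map_operator(bound: str, inclusive: bool) -> str:
    """Map an interval bound to its comparison built-in.

    high/exclusive -> lessThan, high/inclusive -> lessThanOrEqual,
    low/exclusive -> greaterThan, low/inclusive -> greaterThanOrEqual,
    both (degenerate equal-bounds interval) -> equal.
    """
    if bound == "high":
        return "lessThanOrEqual" if inclusive else "lessThan"
    if bound == "low":
        return "greaterThanOrEqual" if inclusive else "greaterThan"
    if bound == "both":
        return "equal"
    raise UsageError(f"no comparison built-in for bound {bound!r}")


def _threshold_range_type(value: float) -> str:
    return "int" if float(value).is_integer() else "decimal"


def compose_rule(
    criterion: HqmfCriterion, dcdo: Ontology, rule_index: int
) -> SwrlRule:
    """Compose the SWRL rule for one criterion against a populated DCDO.

    Body atom order is fixed — patient, value-set class, patient/observation
    link, value, data range, unit, comparison built-in — so that rendered
    rules are deterministic.  The head asserts the per-rule evidence
    individual: ``has_evidence(?x, ev{rule_index})``.
    """
    vs_id = sanitize_name(criterion.value_set_name)
    if vs_id not in dcdo.classes:
        raise CompositionError(
            f"value-set class {vs_id!r} not in the domain ontology; "
            "populate it from the criterion first"
        )
    cmp: Optional[ComparisonSpec] = criterion.comparison
    numeric = cmp is not None and cmp.kind == "numeric"

    x, y, z = var("x"), var("y"), var("z")
    body: list[SwrlAtom] = [
        SwrlAtom("class", str(PATIENT), (x,)),
        SwrlAtom("class", str(vs_id), (y,)),
    ]
    link = HAS_RESULT_COMPARISON if numeric else HAS_RESULT
    body.append(SwrlAtom("individual_property", str(link), (x, y)))

    if numeric:
        body.append(SwrlAtom("data_valued_property", "has_value", (y, z)))
        body.append(SwrlAtom("data_range", _threshold_range_type(cmp.value), (z,)))
        if cmp.unit:
            unit_id = sanitize_name(cmp.unit)
            if unit_id not in dcdo.individuals:
                raise CompositionError(
                    f"unit individual {unit_id!r} not in the domain ontology; "
                    "populate it from the criterion first"
                )
            body.append(SwrlAtom("individual_property", "has_unit", (y, ind(unit_id))))
        builtin = map_operator(cmp.bound, cmp.inclusive)
        body.append(SwrlAtom("builtin", builtin, (z, lit(cmp.value))))
    elif cmp is not None and cmp.kind == "nominal":
        value_id = sanitize_name(cmp.nominal_value)
        body.append(SwrlAtom("individual_property", "has_result", (y, ind(value_id))))

    ev = evidence_individual(dcdo, rule_index)
    head = [SwrlAtom("individual_property", "has_evidence", (x, ind(ev.id)))]
    return SwrlRule(
        rule_id=f"rule{rule_index}",
        body=body,
        head=head,
        source_criterion=criterion.title,
    )


# ---------------------------------------------------------------------------
# Rendering

def _fmt_num(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def _render_arg(arg: Argument) -> str:
    kind, value = arg
    if kind == "var":
        return f"?{value}"
    if kind == "lit":
        return _fmt_num(value)
    return str(value)


def render_atom(atom: SwrlAtom) -> str:
    args = ", ".join(_render_arg(a) for a in atom.arguments)
    return f"{atom.predicate}({args})"


def render_rule(rule: SwrlRule) -> str:
    """Canonical text: comma-separated body, ``->``, comma-separated head."""
    body = ", ".join(render_atom(a) for a in rule.body)
    head = ", ".join(render_atom(a) for a in rule.head)
    return f"{body} -> {head}"


# ---------------------------------------------------------------------------
# Validation

_ILLEGAL_ID_RE = re.compile(r"[\[\]\s]")


def _atom_identifiers(atom: SwrlAtom) -> Iterator[str]:
    yield atom.predicate
    for kind, value in atom.arguments:
        if kind == "ind":
            yield str(value)


def validate_rule(rule: SwrlRule) -> ValidationReport:
    """Syntax-check a rule; returns a report, never raises.

    Checks, in order: identifier legality (no brackets or whitespace),
    the safety condition (every head variable occurs in the body), atom
    arities, known comparison built-ins, and a non-empty head.
    """
    violations: list[Violation] = []
    atoms = list(rule.body) + list(rule.head)

    for atom in atoms:
        for identifier in _atom_identifiers(atom):
            if _ILLEGAL_ID_RE.search(identifier):
                violations.append(Violation(
                    "ILLEGAL_CHAR",
                    "identifier contains an illegal character ('[', ']' or whitespace)",
                    identifier,
                ))

    body_vars = set().union(*(a.variables() for a in rule.body)) if rule.body else set()
    for atom in rule.head:
        for v in sorted(atom.variables() - body_vars):
            violations.append(Violation(
                "UNSAFE_HEAD_VAR",
                f"head variable ?{v} does not occur in the body",
                f"?{v}",
            ))

    for atom in atoms:
        expected = 1 if atom.atom_kind in _UNARY_KINDS else 2
        if len(atom.arguments) != expected:
            violations.append(Violation(
                "MALFORMED_ATOM",
                f"{atom.atom_kind} atom takes {expected} argument(s), "
                f"got {len(atom.arguments)}",
                render_atom(atom),
            ))

    for atom in atoms:
        if atom.atom_kind == "builtin" and atom.predicate not in SUPPORTED_BUILTINS:
            violations.append(Violation(
                "UNKNOWN_BUILTIN",
                f"unsupported built-in {atom.predicate!r}",
                atom.predicate,
            ))

    if not rule.head:
        violations.append(Violation("EMPTY_HEAD", "rule head is empty", rule.rule_id))

    return ValidationReport(valid=not violations, violations=violations)


# ---------------------------------------------------------------------------
# Evaluation (single-rule forward chaining over toy fact sets)

@dataclass
class FactSet:
    """Ground facts to evaluate a rule against.

    Class assertions are (individual, class); property assertions are
    (subject, property, object-individual); data assertions are
    (subject, property, numeric literal).  ``add_data`` optionally records
    the observation's unit as a ``has_unit`` property assertion, which is
    how rules test units (exact unit-individual match).
    """

    class_assertions: set[tuple[str, str]] = field(default_factory=set)
    property_assertions: set[tuple[str, str, str]] = field(default_factory=set)
    data_assertions: set[tuple[str, str, float]] = field(default_factory=set)

    def add_class(self, individual: str, cls: str) -> None:
        self.class_assertions.add((individual, str(cls)))

    def add_property(self, subject: str, prop: str, obj: str) -> None:
        self.property_assertions.add((subject, str(prop), obj))

    def add_data(self, subject: str, prop: str, value: float,
                 unit: Optional[str] = None) -> None:
        self.data_assertions.add((subject, str(prop), float(value)))
        if unit is not None:
            self.add_property(subject, "has_unit", str(sanitize_name(unit)))


Binding = dict[str, Union[str, float]]


def _match_term(arg: Argument, ground: Union[str, float],
                binding: Binding) -> Optional[Binding]:
    kind, value = arg
    if kind == "var":
        if value in binding:
            return binding if binding[value] == ground else None
        new = dict(binding)
        new[value] = ground
        return new
    expected = value if kind == "ind" else float(value)
    return binding if expected == ground else None


def _extend(atom: SwrlAtom, facts: FactSet, binding: Binding) -> Iterator[Binding]:
    if atom.atom_kind == "class":
        for individual, cls in facts.class_assertions:
            if cls == atom.predicate:
                b = _match_term(atom.arguments[0], individual, binding)
                if b is not None:
                    yield b
    elif atom.atom_kind == "individual_property":
        for s, p, o in facts.property_assertions:
            if p == atom.predicate:
                b = _match_term(atom.arguments[0], s, binding)
                if b is not None:
                    b = _match_term(atom.arguments[1], o, b)
                    if b is not None:
                        yield b
    elif atom.atom_kind == "data_valued_property":
        for s, p, v in facts.data_assertions:
            if p == atom.predicate:
                b = _match_term(atom.arguments[0], s, binding)
                if b is not None:
                    b = _match_term(atom.arguments[1], v, b)
                    if b is not None:
                        yield b
    elif atom.atom_kind == "data_range":
        bound = _resolve(atom.arguments[0], binding)
        if isinstance(bound, float) and (
            atom.predicate != "int" or bound.is_integer()
        ):
            yield binding
    elif atom.atom_kind == "builtin":
        a = _resolve(atom.arguments[0], binding)
        b = _resolve(atom.arguments[1], binding)
        if (
            isinstance(a, float) and isinstance(b, float)
            and _BUILTIN_PYTHON[atom.predicate](a, b)
        ):
            yield binding
    elif atom.atom_kind == "same_individual":
        a = _resolve(atom.arguments[0], binding)
        b = _resolve(atom.arguments[1], binding)
        if a is not None and a == b:
            yield binding
    elif atom.atom_kind == "different_individual":
        a = _resolve(atom.arguments[0], binding)
        b = _resolve(atom.arguments[1], binding)
        if a is not None and b is not None and a != b:
            yield binding


def _resolve(arg: Argument, binding: Binding) -> Union[str, float, None]:
    kind, value = arg
    if kind == "var":
        return binding.get(value)
    return float(value) if kind == "lit" else value


def evaluate_rule(rule: SwrlRule, facts: FactSet) -> set[tuple[str, str, str]]:
    """Forward-chain one valid rule over a fact set.

    Every variable binding satisfying all body atoms instantiates the head;
    returns the set of inferred (subject, property, object) assertions.
    No recursion: inferred facts are not fed back.
    """
    report = validate_rule(rule)
    if not report.valid:
        codes = ", ".join(v.code for v in report.violations)
        raise UsageError(f"cannot evaluate an invalid rule ({codes})")

    bindings: list[Binding] = [{}]
    for atom in rule.body:
        bindings = [b2 for b in bindings for b2 in _extend(atom, facts, b)]
        if not bindings:
            return set()

    inferred: set[tuple[str, str, str]] = set()
    for binding in bindings:
        for atom in rule.head:
            s = _resolve(atom.arguments[0], binding)
            o = _resolve(atom.arguments[1], binding)
            inferred.add((str(s), atom.predicate, str(o)))
    return inferred


# ---------------------------------------------------------------------------
# SWRL-in-OWL serialization (standard SWRL RDF vocabulary)

SWRL = Namespace("http://www.w3.org/2003/11/swrl#")
SWRLB = Namespace("http://www.w3.org/2003/11/swrlb#")
_VAR_NS = "urn:swrl#"

_ATOM_TYPES = {
    "class": SWRL.ClassAtom,
    "individual_property": SWRL.IndividualPropertyAtom,
    "data_valued_property": SWRL.DatavaluedPropertyAtom,
    "builtin": SWRL.BuiltinAtom,
    "data_range": SWRL.DataRangeAtom,
    "same_individual": SWRL.SameIndividualAtom,
    "different_individual": SWRL.DifferentIndividualsAtom,
}

_DATA_RANGES = {"int": XSD.int, "decimal": XSD.decimal}


def _rdf_term(arg: Argument, dcdo: Ontology, g: Graph):
    kind, value = arg
    if kind == "var":
        v = URIRef(_VAR_NS + value)
        g.add((v, RDF.type, SWRL.Variable))
        return v
    if kind == "lit":
        return RdfLiteral(int(value)) if float(value).is_integer() else RdfLiteral(value)
    return URIRef(ENTITY_NS + quote(str(value), safe=""))


def _class_ref(name: str, dcdo: Ontology) -> URIRef:
    cls = dcdo.classes.get(Identifier(name))
    ns = NAMESPACES[cls.prefix] if cls is not None else NAMESPACES["DCDO"]
    return URIRef(ns + quote(name, safe=""))


class _NodeMinter:
    """Deterministic blank-node labels so serialized output is stable."""

    def __init__(self, prefix: str):
        self.prefix = prefix
        self.n = 0

    def __call__(self) -> BNode:
        self.n += 1
        return BNode(f"{self.prefix}_n{self.n}")


def _rdf_list(g: Graph, items: list, mint: _NodeMinter, node_type=None):
    if not items:
        return RDF.nil
    head = mint()
    node = head
    for i, item in enumerate(items):
        if node_type is not None:
            g.add((node, RDF.type, node_type))
        g.add((node, RDF.first, item))
        rest = mint() if i < len(items) - 1 else RDF.nil
        g.add((node, RDF.rest, rest))
        node = rest
    return head


def _atom_node(atom: SwrlAtom, dcdo: Ontology, g: Graph, mint: _NodeMinter) -> BNode:
    node = mint()
    g.add((node, RDF.type, _ATOM_TYPES[atom.atom_kind]))
    if atom.atom_kind == "class":
        g.add((node, SWRL.classPredicate, _class_ref(atom.predicate, dcdo)))
        g.add((node, SWRL.argument1, _rdf_term(atom.arguments[0], dcdo, g)))
    elif atom.atom_kind == "data_range":
        g.add((node, SWRL.dataRange, _DATA_RANGES.get(atom.predicate, XSD.decimal)))
        g.add((node, SWRL.argument1, _rdf_term(atom.arguments[0], dcdo, g)))
    elif atom.atom_kind == "builtin":
        g.add((node, SWRL.builtin, SWRLB[atom.predicate]))
        args = [_rdf_term(a, dcdo, g) for a in atom.arguments]
        g.add((node, SWRL.arguments, _rdf_list(g, args, mint)))
    else:
        g.add((node, SWRL.propertyPredicate,
               URIRef(ENTITY_NS + quote(atom.predicate, safe=""))))
        g.add((node, SWRL.argument1, _rdf_term(atom.arguments[0], dcdo, g)))
        g.add((node, SWRL.argument2, _rdf_term(atom.arguments[1], dcdo, g)))
    return node


def add_rules_to_graph(g: Graph, rules: Sequence[SwrlRule], dcdo: Ontology) -> None:
    """Embed rules into an RDF graph using the SWRL RDF vocabulary."""
    g.bind("swrl", SWRL)
    g.bind("swrlb", SWRLB)
    for rule in rules:
        imp = URIRef(ENTITY_NS + quote(rule.rule_id, safe=""))
        mint = _NodeMinter(rule.rule_id)
        g.add((imp, RDF.type, SWRL.Imp))
        body = [_atom_node(a, dcdo, g, mint) for a in rule.body]
        head = [_atom_node(a, dcdo, g, mint) for a in rule.head]
        g.add((imp, SWRL.body, _rdf_list(g, body, mint, SWRL.AtomList)))
        g.add((imp, SWRL.head, _rdf_list(g, head, mint, SWRL.AtomList)))


def serialize_rules_owl(
    rules: Sequence[SwrlRule], dcdo: Ontology, format: str = "rdfxml"
) -> str:
    """The DCDO plus embedded SWRL rules as one OWL document."""
    from dxcriteria.ontology_core import serialize_graph

    g = ontology_to_graph(dcdo)
    add_rules_to_graph(g, rules, dcdo)
    return serialize_graph(g, format)
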