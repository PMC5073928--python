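"""Construct, edit, count and serialize diagnostic-criteria ontologies.

The upper ontology (DCUO) merges two standard information models: the
ICD-11 content model, whose 13 parameters (plus the manifestation
sub-elements *Investigation Findings* and *Signs and Symptoms*) form the
class backbone, and the Quality Data Model (QDM), whose 10 commonly used
datatypes are placed as subclasses of the matching content-model elements.
Three further classes (Patient, Unit, Evidence) and seven properties
support rule construction.  Disease-specific domain ontologies (DCDOs)
extend this schema; see :mod:`dxcriteria.dcdo_populator`.

Ontologies are plain in-memory data structures, serialized to OWL 2
(RDF/XML or Turtle) through rdflib.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Literal, Optional
from urllib.parse import quote, unquote

from rdflib import Graph, Literal as RdfLiteral, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL

from dxcriteria.errors import InvalidNameError, OntologyError, UsageError

Prefix = Literal["ICD", "QDM", "DCUO", "DCDO"]
PropertyKind = Literal["object", "data", "annotation"]

#: Namespace IRI for each class prefix, plus shared property/individual space.
NAMESPACES: dict[str, str] = {
    "ICD": "https://w3id.org/dxcriteria/icd#",
    "QDM": "https://w3id.org/dxcriteria/qdm#",
    "DCUO": "https://w3id.org/dxcriteria/dcuo#",
    "DCDO": "https://w3id.org/dxcriteria/dcdo#",
}
#: Properties and individuals live in the DCUO namespace regardless of origin.
ENTITY_NS = NAMESPACES["DCUO"]

DCUO_IRI = "https://w3id.org/dxcriteria/dcuo"


class Identifier(str):
    """A sanitized ontology name.

    Identifiers never contain whitespace: every whitespace run in the raw
    source must have been replaced (see :func:`sanitize_name`) before
    construction.  Square brackets are *not* rejected here — they are
    carried through so that rule validation can detect and reject them
    (the '[copies]/mL' unit failure mode).
    """

    def __new__(cls, value: str) -> "Identifier":
        if not value:
            raise InvalidNameError("identifier must be non-empty")
        if re.search(r"\s", value):
            raise InvalidNameError(
                f"identifier contains whitespace: {value!r}; sanitize first"
            )
        return super().__new__(cls, value)


def sanitize_name(raw: str) -> Identifier:
    """Turn a display name into an ontology identifier.

    Whitespace runs become a single underscore; parentheses become
    underscores, with underscore runs collapsed and trailing underscores
    trimmed.  Word characters plus ``. / - ,`` pass through unchanged.
    Square brackets are preserved verbatim so that downstream rule
    validation can flag them.  The mapping is idempotent.

    >>> sanitize_name("High Density Lipoprotein (HDL)")
    'High_Density_Lipoprotein_HDL'
    >>> sanitize_name("Laboratory Test, Result")
    'Laboratory_Test,_Result'
    """
    if not raw or not raw.strip():
        raise InvalidNameError("cannot sanitize an empty name")
    out = re.sub(r"[\s()]+", "_", raw)
    out = re.sub(r"_+", "_", out).rstrip("_")
    if not out:
        raise InvalidNameError(f"name reduces to nothing after sanitization: {raw!r}")
    return Identifier(out)


@dataclass(frozen=True)
class AnnotationAssertion:
    """An annotation triple: *subject* *property* "value"."""

    subject: Identifier
    property: Identifier
    value: str


@dataclass
class ClassDef:
    id: Identifier
    label: str
    prefix: Prefix
    parent: Optional[Identifier] = None


@dataclass
class PropertyDef:
    id: Identifier
    kind: PropertyKind
    parent: Optional[Identifier] = None


@dataclass
class IndividualDef:
    id: Identifier
    member_of: Optional[Identifier] = None


@dataclass
class ElementCounts:
    """Structural tally of an ontology (roots vs subclasses, properties)."""

    root_classes: int
    subclasses: int
    object_properties: int
    data_properties: int
    per_prefix: dict[str, int]

    @property
    def total_classes(self) -> int:
        return self.root_classes + self.subclasses


@dataclass
class Ontology:
    """In-memory class/property/individual/annotation graph.

    Invariants enforced on edit: identifiers unique within their category,
    subclass parents exist, the subclass graph is acyclic, sub-property
    links join properties of the same kind, individuals belong to existing
    classes, and annotation subjects name existing entities.
    """

    namespace_iri: str = DCUO_IRI
    classes: dict[Identifier, ClassDef] = field(default_factory=dict)
    properties: dict[Identifier, PropertyDef] = field(default_factory=dict)
    individuals: dict[Identifier, IndividualDef] = field(default_factory=dict)
    annotations: list[AnnotationAssertion] = field(default_factory=list)

    # -- edits ---------------------------------------------------------

    def add_class(self, cls: ClassDef) -> None:
        if cls.id in self.classes:
            raise OntologyError(f"duplicate class {cls.id}")
        if cls.parent is not None and cls.parent not in self.classes:
            raise OntologyError(f"parent class {cls.parent} of {cls.id} not found")
        self.classes[cls.id] = cls
        self._check_acyclic(cls.id)

    def add_property(self, prop: PropertyDef) -> None:
        if prop.id in self.properties:
            raise OntologyError(f"duplicate property {prop.id}")
        if prop.parent is not None:
            parent = self.properties.get(prop.parent)
            if parent is None:
                raise OntologyError(f"parent property {prop.parent} not found")
            if parent.kind != prop.kind:
                raise OntologyError(
                    f"sub-property {prop.id} ({prop.kind}) cannot specialize "
                    f"{parent.id} ({parent.kind})"
                )
        self.properties[prop.id] = prop

    def add_individual(self, ind: IndividualDef) -> None:
        if ind.id in self.individuals:
            raise OntologyError(f"duplicate individual {ind.id}")
        if ind.member_of is not None and ind.member_of not in self.classes:
            raise OntologyError(f"class {ind.member_of} of individual {ind.id} not found")
        self.individuals[ind.id] = ind

    def annotate(self, assertion: AnnotationAssertion) -> None:
        if not (
            assertion.subject in self.classes
            or assertion.subject in self.properties
            or assertion.subject in self.individuals
        ):
            raise OntologyError(f"annotation subject {assertion.subject} not found")
        if assertion not in self.annotations:
            self.annotations.append(assertion)

    def _check_acyclic(self, start: Identifier) -> None:
        seen = set()
        node: Optional[Identifier] = start
        while node is not None:
            if node in seen:
                raise OntologyError(f"subclass cycle through {start}")
            seen.add(node)
            node = self.classes[node].parent if node in self.classes else None

    # -- queries -------------------------------------------------------

    def subclasses_of(self, parent: Identifier) -> list[ClassDef]:
        return [c for c in self.classes.values() if c.parent == parent]

    def classes_with_prefix(self, prefix: str) -> list[ClassDef]:
        return [c for c in self.classes.values() if c.prefix == prefix]

    def copy(self) -> "Ontology":
        return Ontology(
            namespace_iri=self.namespace_iri,
            classes={k: replace(v) for k, v in self.classes.items()},
            properties={k: replace(v) for k, v in self.properties.items()},
            individuals={k: replace(v) for k, v in self.individuals.items()},
            annotations=list(self.annotations),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return (
            self.namespace_iri == other.namespace_iri
            and self.classes == other.classes
            and self.properties == other.properties
            and self.individuals == other.individuals
            and set(self.annotations) == set(other.annotations)
        )

    def is_extension_of(self, base: "Ontology") -> bool:
        """True when every element of *base* is present, unmodified, here."""
        return (
            all(self.classes.get(k) == v for k, v in base.classes.items())
            and all(self.properties.get(k) == v for k, v in base.properties.items())
            and all(self.individuals.get(k) == v for k, v in base.individuals.items())
            and set(base.annotations) <= set(self.annotations)
        )


# ---------------------------------------------------------------------------
# Upper ontology construction

#: The 13 main parameters of the ICD-11 content model.  "ICD Entity Title"
#: is modeled as the class "Title" (the target of the Diagnostic, Active
#: subclass mapping).
ICD_CONTENT_MODEL_PARAMETERS: tuple[tuple[str, str], ...] = (
    ("Title", "ICD Entity Title"),
    ("Classification_Properties", "Classification Properties"),
    ("Textual_Definitions", "Textual Definitions"),
    ("Terms", "Terms"),
    ("Body_System/Structure_Description", "Body System/Structure Description"),
    ("Temporal_Properties", "Temporal Properties"),
    ("Severity_of_Subtypes_Properties", "Severity of Subtypes Properties"),
    ("Manifestation_Properties", "Manifestation Properties"),
    ("Causal_Properties", "Causal Properties"),
    ("Functioning_Properties", "Functioning Properties"),
    ("Specific_Condition_Properties", "Specific Condition Properties"),
    ("Treatment_Properties", "Treatment Properties"),
    ("Diagnostic_Criteria", "Diagnostic Criteria"),
)

#: QDM datatype -> parent ICD content-model element (display names).
QDM_DATATYPE_PARENTS: dict[str, str] = {
    "Laboratory Test, Result": "Investigation Findings",
    "Diagnostic Study, Performed": "Investigation Findings",
    "Diagnostic, Active": "Title",
    "Physical Exam, Performed": "Investigation Findings",
    "Symptom, Active": "Signs and Symptoms",
    "Medication, Active": "Treatment Properties",
    "Patient Characteristic Birth Date": "Specific Condition Properties",
    "Patient Characteristic Race": "Specific Condition Properties",
    "Patient Characteristic Sex": "Specific Condition Properties",
    "Procedure, Recommended": "Treatment Properties",
}

#: Object properties derived from the four QDM attributes (result, method,
#: reason, severity) plus the unit and evidence links.
DCUO_OBJECT_PROPERTIES = (
    "has_result",
    "has_method",
    "has_reason",
    "has_severity",
    "has_unit",
    "has_evidence",
)

HAS_VALUE = Identifier("has_value")

PATIENT = Identifier("Patient")
UNIT = Identifier("Unit")
EVIDENCE = Identifier("Evidence")


def build_dcuo() -> Ontology:
    """Build the diagnostic-criteria upper ontology.

    Deterministic constructor: the 13 ICD content-model parameter classes
    plus *Investigation Findings* and *Signs and Symptoms* (children of
    Manifestation Properties); the 10 QDM datatype classes as subclasses of
    their content-model elements; the rule-support classes Patient, Unit
    and Evidence; 6 object properties and the data property has_value.
    """
    ont = Ontology(namespace_iri=DCUO_IRI)
    for ident, label in ICD_CONTENT_MODEL_PARAMETERS:
        ont.add_class(ClassDef(Identifier(ident), label, "ICD"))
    manifestation = Identifier("Manifestation_Properties")
    for label in ("Investigation Findings", "Signs and Symptoms"):
        ont.add_class(
            ClassDef(sanitize_name(label), label, "ICD", parent=manifestation)
        )
    for datatype, parent_label in QDM_DATATYPE_PARENTS.items():
        ont.add_class(
            ClassDef(
                sanitize_name(datatype),
                datatype,
                "QDM",
                parent=sanitize_name(parent_label),
            )
        )
    for name in (PATIENT, UNIT, EVIDENCE):
        ont.add_class(ClassDef(name, str(name), "DCUO"))
    for name in DCUO_OBJECT_PROPERTIES:
        ont.add_property(PropertyDef(Identifier(name), "object"))
    ont.add_property(PropertyDef(HAS_VALUE, "data"))
    return ont


def count_elements(ont: Ontology) -> ElementCounts:
    """Tally roots, subclasses and properties; classes also per prefix."""
    roots = sum(1 for c in ont.classes.values() if c.parent is None)
    per_prefix: dict[str, int] = {}
    for c in ont.classes.values():
        per_prefix[c.prefix] = per_prefix.get(c.prefix, 0) + 1
    return ElementCounts(
        root_classes=roots,
        subclasses=len(ont.classes) - roots,
        object_properties=sum(1 for p in ont.properties.values() if p.kind == "object"),
        data_properties=sum(1 for p in ont.properties.values() if p.kind == "data"),
        per_prefix=per_prefix,
    )


# ---------------------------------------------------------------------------
# OWL serialization (rdflib)

_PARSE_FORMATS = {"rdfxml": "xml", "turtle": "turtle"}
_FORMATS = frozenset(_PARSE_FORMATS)

_PREFIX_BY_NS = {v: k for k, v in NAMESPACES.items()}


def _class_iri(cls: ClassDef) -> URIRef:
    return URIRef(NAMESPACES[cls.prefix] + quote(str(cls.id), safe=""))


def _entity_iri(ident: Identifier) -> URIRef:
    return URIRef(ENTITY_NS + quote(str(ident), safe=""))


_PROP_TYPES = {
    "object": OWL.ObjectProperty,
    "data": OWL.DatatypeProperty,
    "annotation": OWL.AnnotationProperty,
}


def ontology_to_graph(ont: Ontology) -> Graph:
    """Render an :class:`Ontology` as an rdflib OWL graph."""
    g = Graph()
    for prefix, ns in NAMESPACES.items():
        g.bind(prefix.lower(), Namespace(ns))
    g.bind("owl", OWL)
    onto_node = URIRef(ont.namespace_iri)
    g.add((onto_node, RDF.type, OWL.Ontology))

    class_iris = {c.id: _class_iri(c) for c in ont.classes.values()}
    for cls in ont.classes.values():
        iri = class_iris[cls.id]
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, RDFS.label, RdfLiteral(cls.label)))
        if cls.parent is not None:
            g.add((iri, RDFS.subClassOf, class_iris[cls.parent]))
    for prop in ont.properties.values():
        iri = _entity_iri(prop.id)
        g.add((iri, RDF.type, _PROP_TYPES[prop.kind]))
        if prop.parent is not None:
            g.add((iri, RDFS.subPropertyOf, _entity_iri(prop.parent)))
    for ind in ont.individuals.values():
        iri = _entity_iri(ind.id)
        g.add((iri, RDF.type, OWL.NamedIndividual))
        if ind.member_of is not None:
            g.add((iri, RDF.type, class_iris[ind.member_of]))
    for ann in ont.annotations:
        subj_cls = ont.classes.get(ann.subject)
        subj = class_iris[ann.subject] if subj_cls is not None else _entity_iri(ann.subject)
        g.add((subj, _entity_iri(ann.property), RdfLiteral(ann.value)))
    return g


def serialize_graph(g: Graph, format: str) -> str:
    """Serialize an rdflib graph to canonical, byte-stable OWL text.

    rdflib's element ordering varies with the per-process hash seed; the
    Turtle serializer sorts subjects itself, and RDF/XML output is
    canonicalized by sorting subject and property elements.
    """
    if format not in _FORMATS:
        raise UsageError(
            f"unknown format {format!r}; expected one of {sorted(_FORMATS)}"
        )
    if format == "turtle":
        return g.serialize(format="turtle")
    return _canonical_rdfxml(g.serialize(format="xml"))


def _canonical_rdfxml(text: str) -> str:
    """Sort the flat RDF/XML emitted by rdflib into a canonical element order."""
    from lxml import etree

    parser = etree.XMLParser(remove_blank_text=True)
    root = etree.fromstring(text.encode("utf-8"), parser)
    for description in root:
        description[:] = sorted(
            description, key=lambda e: etree.tostring(e)
        )
    rdf_ns = "{http://www.w3.org/1999/02/22-rdf-syntax-ns#}"
    root[:] = sorted(
        root,
        key=lambda e: (
            e.get(rdf_ns + "about") or e.get(rdf_ns + "nodeID") or "",
            etree.tostring(e),
        ),
    )
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def serialize_ontology(ont: Ontology, format: str = "rdfxml") -> str:
    """Serialize to OWL text; ``format`` is ``rdfxml`` or ``turtle``."""
    return serialize_graph(ontology_to_graph(ont), format)


def _split_iri(iri: URIRef) -> tuple[Optional[str], Identifier]:
    text = str(iri)
    for ns, prefix in _PREFIX_BY_NS.items():
        if text.startswith(ns):
            return prefix, Identifier(unquote(text[len(ns):]))
    return None, Identifier(unquote(text.rsplit("#", 1)[-1]))


def parse_ontology(text: str, format: str = "rdfxml") -> Ontology:
    """Parse an OWL document produced by :func:`serialize_ontology`.

    Round-trip identity holds on classes, properties, individuals and
    annotations.
    """
    if format not in _PARSE_FORMATS:
        raise UsageError(
            f"unknown format {format!r}; expected one of {sorted(_PARSE_FORMATS)}"
        )
    g = Graph()
    g.parse(data=text, format=_PARSE_FORMATS[format])

    namespace_iri = DCUO_IRI
    for s in g.subjects(RDF.type, OWL.Ontology):
        namespace_iri = str(s)
    ont = Ontology(namespace_iri=namespace_iri)

    prop_kind_by_type = {v: k for k, v in _PROP_TYPES.items()}
    prop_iris: dict[URIRef, PropertyDef] = {}
    for rdf_type, kind in prop_kind_by_type.items():
        for s in g.subjects(RDF.type, rdf_type):
            _, ident = _split_iri(s)
            prop_iris[s] = PropertyDef(ident, kind)
    for iri, prop in prop_iris.items():
        parent = g.value(iri, RDFS.subPropertyOf)
        if parent is not None:
            prop.parent = _split_iri(parent)[1]

    class_defs: dict[URIRef, ClassDef] = {}
    for s in g.subjects(RDF.type, OWL.Class):
        if not isinstance(s, URIRef):
            continue
        prefix, ident = _split_iri(s)
        label = g.value(s, RDFS.label)
        class_defs[s] = ClassDef(ident, str(label) if label else str(ident), prefix or "DCDO")
    for iri, cls in class_defs.items():
        parent = g.value(iri, RDFS.subClassOf)
        if parent is not None:
            cls.parent = _split_iri(parent)[1]
    # topological insert so parent-exists checks pass
    pending = dict(class_defs)
    while pending:
        progressed = False
        for iri, cls in list(pending.items()):
            if cls.parent is None or cls.parent in ont.classes:
                ont.add_class(cls)
                del pending[iri]
                progressed = True
        if not progressed:
            raise OntologyError("unresolvable subclass references in document")

    ordered_props = sorted(prop_iris.values(), key=lambda p: p.parent is not None)
    for prop in ordered_props:
        ont.add_property(prop)

    for s in g.subjects(RDF.type, OWL.NamedIndividual):
        _, ident = _split_iri(s)
        member = None
        for t in g.objects(s, RDF.type):
            if t != OWL.NamedIndividual and t in class_defs:
                member = class_defs[t].id
        ont.add_individual(IndividualDef(ident, member_of=member))

    annotation_props = {
        iri for iri, p in prop_iris.items() if p.kind == "annotation"
    }
    for s, p, o in g:
        if p in annotation_props and isinstance(o, RdfLiteral):
            ont.annotate(
                AnnotationAssertion(_split_iri(s)[1], _split_iri(p)[1], str(o))
            )
    return ont
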