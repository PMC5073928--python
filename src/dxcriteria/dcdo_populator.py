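"""Populate a disease-specific domain ontology (DCDO) from parsed criteria.

The upper ontology fixes the schema; a DCDO extends it with the
disease-specific value-set classes, terminology annotations, unit
individuals and evidence individuals that a concrete set of criteria
needs.  Population is a monotone, idempotent extension: nothing in the
upper ontology is removed or renamed, and applying the same criterion
twice changes nothing.

Mapping per criterion:

1. the value-set name becomes a subclass of its QDM datatype class;
2. the datatype-level coded concept is recorded as annotations of the
   datatype class (code / displayName / codeSystem);
3. the value-set OID, its code system and display name annotate the new
   value-set class;
4. a numeric result comparison adds the object property
   ``has_result_comparison`` as a sub-property of ``has_result`` (with the
   SNOMED-CT "result" concept annotating ``has_result`` and the IVL_PQ
   value type annotating the comparison property);
5. a unit string becomes an individual of class ``Unit``;
6. a numeric threshold is logged as a use of the data property
   ``has_value``; a nominal result value becomes an individual of the
   artifact class ``ResultValue``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Union

from dxcriteria.errors import UnknownDatatypeError, UsageError
from dxcriteria.hqmf_io import SUPPORTED_TEMPLATE_OIDS, HqmfCriterion
from dxcriteria.ontology_core import (
    EVIDENCE,
    HAS_VALUE,
    UNIT,
    AnnotationAssertion,
    ClassDef,
    Identifier,
    IndividualDef,
    Ontology,
    PropertyDef,
    sanitize_name,
)
from dxcriteria.errors import UnsupportedTemplateError

HAS_RESULT = Identifier("has_result")
HAS_RESULT_COMPARISON = Identifier("has_result_comparison")
RESULT_VALUE_CLASS = Identifier("ResultValue")

#: Annotation property identifiers (the mapping rules name the annotation
#: values; these property keys are this implementation's own).
ANN_CODE = Identifier("code")
ANN_CODE_SYSTEM = Identifier("codeSystem")
ANN_CODE_SYSTEM_NAME = Identifier("codeSystemName")
ANN_DISPLAY_NAME = Identifier("displayName")
ANN_VALUE_SET_OID = Identifier("valueSetOID")
ANN_VALUE_TYPE = Identifier("valueType")

ANNOTATION_PROPERTIES = (
    ANN_CODE, ANN_CODE_SYSTEM, ANN_CODE_SYSTEM_NAME,
    ANN_DISPLAY_NAME, ANN_VALUE_SET_OID, ANN_VALUE_TYPE,
)

#: Code system OID annotated on value-set classes.
VALUE_SET_CODE_SYSTEM = "2.16.840.1.113883.3.560.101.1"

EditAction = Literal[
    "add_subclass",
    "add_annotation",
    "add_object_property",
    "add_subproperty",
    "add_individual",
    "add_data_property_use",
]


@dataclass(frozen=True)
class OntologyEdit:
    """One population step; replaying the same edit is a no-op."""

    action: EditAction
    payload: Union[ClassDef, PropertyDef, IndividualDef, AnnotationAssertion, tuple]

    def to_json_line(self) -> str:
        import json
        from dataclasses import asdict, is_dataclass

        payload = asdict(self.payload) if is_dataclass(self.payload) else list(self.payload)
        return json.dumps({"action": self.action, "payload": payload})


class _EditLog:
    """Applies edits to an ontology, recording only actual changes."""

    def __init__(self, ont: Ontology):
        self.ont = ont
        self.edits: list[OntologyEdit] = []

    def add_class(self, cls: ClassDef, action: EditAction = "add_subclass") -> None:
        if cls.id not in self.ont.classes:
            self.ont.add_class(cls)
            self.edits.append(OntologyEdit(action, cls))

    def add_property(self, prop: PropertyDef) -> None:
        if prop.id not in self.ont.properties:
            self.ont.add_property(prop)
            action: EditAction = (
                "add_subproperty" if prop.parent is not None else "add_object_property"
            )
            self.edits.append(OntologyEdit(action, prop))

    def add_individual(self, ind: IndividualDef) -> None:
        if ind.id not in self.ont.individuals:
            self.ont.add_individual(ind)
            self.edits.append(OntologyEdit("add_individual", ind))

    def annotate(self, subject: Identifier, prop: Identifier, value: str) -> None:
        assertion = AnnotationAssertion(subject, prop, value)
        if assertion not in self.ont.annotations:
            self.ont.annotate(assertion)
            self.edits.append(OntologyEdit("add_annotation", assertion))

    def record_value_use(self, value: float) -> None:
        edit = OntologyEdit("add_data_property_use", (str(HAS_VALUE), value))
        if edit not in self.edits:
            self.edits.append(edit)


def _ensure_annotation_properties(log: _EditLog) -> None:
    for prop in ANNOTATION_PROPERTIES:
        if prop not in log.ont.properties:
            log.ont.add_property(PropertyDef(prop, "annotation"))


def populate_dcdo(
    dcuo: Ontology, criteria: Sequence[HqmfCriterion]
) -> tuple[Ontology, list[OntologyEdit]]:
    """Extend a copy of the upper ontology with criterion-specific elements.

    Returns the populated domain ontology and the edit log.  The input
    ontology is not mutated.  Every criterion's datatype must name a QDM
    class of the upper ontology (after name sanitization), and its template
    OID must be in the supported inventory.
    """
    dcdo = dcuo.copy()
    log = _EditLog(dcdo)
    _ensure_annotation_properties(log)

    qdm_classes = {c.id: c for c in dcdo.classes.values() if c.prefix == "QDM"}

    for criterion in criteria:
        if criterion.template_oid not in SUPPORTED_TEMPLATE_OIDS:
            raise UnsupportedTemplateError(criterion.template_oid)
        datatype_id = sanitize_name(criterion.datatype_name)
        if datatype_id not in qdm_classes:
            raise UnknownDatatypeError(
                criterion.datatype_name,
                [c.label for c in qdm_classes.values()],
            )

        # value-set class under its datatype
        value_set_id = sanitize_name(criterion.value_set_name)
        log.add_class(ClassDef(
            value_set_id, criterion.value_set_name, "DCDO", parent=datatype_id,
        ))

        # datatype-level coded concept annotations
        dc = criterion.datatype_code
        log.annotate(datatype_id, ANN_CODE, dc.code)
        if dc.display_name:
            log.annotate(datatype_id, ANN_DISPLAY_NAME, dc.display_name)
        log.annotate(datatype_id, ANN_CODE_SYSTEM, dc.code_system)

        # value-set-level annotations
        log.annotate(value_set_id, ANN_VALUE_SET_OID, criterion.value_set_oid)
        log.annotate(value_set_id, ANN_CODE_SYSTEM, VALUE_SET_CODE_SYSTEM)
        if criterion.value_set_display:
            log.annotate(value_set_id, ANN_DISPLAY_NAME, criterion.value_set_display)

        cmp = criterion.comparison
        if cmp is None:
            continue
        if cmp.kind == "numeric":
            log.add_property(PropertyDef(
                HAS_RESULT_COMPARISON, "object", parent=HAS_RESULT,
            ))
            log.annotate(HAS_RESULT, ANN_CODE, "385676005")
            log.annotate(HAS_RESULT, ANN_CODE_SYSTEM, "2.16.840.1.113883.6.96")
            log.annotate(HAS_RESULT, ANN_CODE_SYSTEM_NAME, "SNOMED-CT")
            log.annotate(HAS_RESULT, ANN_DISPLAY_NAME, "result")
            log.annotate(HAS_RESULT_COMPARISON, ANN_VALUE_TYPE, "IVL_PQ")
            if cmp.unit:
                log.add_individual(IndividualDef(sanitize_name(cmp.unit), member_of=UNIT))
            if cmp.value is not None:
                log.record_value_use(cmp.value)
        elif cmp.kind == "nominal":
            log.add_class(ClassDef(RESULT_VALUE_CLASS, "ResultValue", "DCDO"))
            log.add_individual(IndividualDef(
                sanitize_name(cmp.nominal_value), member_of=RESULT_VALUE_CLASS,
            ))
        # "present" constrains existence only; no further elements needed

    return dcdo, log.edits


def evidence_individual(dcdo: Ontology, rule_index: int) -> IndividualDef:
    """Register (idempotently) the evidence individual ``ev{rule_index}``."""
    if rule_index < 1:
        raise UsageError(f"rule_index must be >= 1, got {rule_index}")
    ident = Identifier(f"ev{rule_index}")
    existing = dcdo.individuals.get(ident)
    if existing is not None:
        return existing
    ind = IndividualDef(ident, member_of=EVIDENCE)
    dcdo.add_individual(ind)
    return ind


def edits_to_json_lines(edits: Sequence[OntologyEdit]) -> str:
    """Edit log as JSON lines (one edit per line)."""
    return "\n".join(e.to_json_line() for e in edits)
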