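"""Parse HQMF R1 XML criterion documents.

A criterion document carries one observation per quality-measure data
criterion.  The outer observation is identified by a *templateId* OID that
names the QDM datatype pattern (e.g. ``2.16.840.1.113883.3.560.1.12`` =
"Laboratory Test, Result"); a nested observation identified by one of the
result templates (``...1019.1`` result/is-present, ``...1019.2``
result/value-set, ``...1019.3`` result/comparison) constrains the result.

Matching is namespace-agnostic on local element names, so documents with
or without the HL7 namespace parse identically.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from typing import Literal, Optional

from lxml import etree

from dxcriteria.errors import (
    ComparisonFormatError,
    HqmfParseError,
    TitleFormatError,
    UnsupportedTemplateError,
)

# Template OIDs of the supported HQMF R1 inventory.
OID_LAB_RESULT = "2.16.840.1.113883.3.560.1.12"
OID_PATIENT_SEX = "2.16.840.1.113883.3.560.1.402"
OID_BIRTH_DATE = "2.16.840.1.113883.3.560.1.400"
OID_RESULT_PRESENT = "2.16.840.1.113883.3.560.1.1019.1"
OID_RESULT_VALUESET = "2.16.840.1.113883.3.560.1.1019.2"
OID_RESULT_COMPARISON = "2.16.840.1.113883.3.560.1.1019.3"

CRITERION_TEMPLATE_OIDS = frozenset({OID_LAB_RESULT, OID_PATIENT_SEX, OID_BIRTH_DATE})
RESULT_TEMPLATE_OIDS = frozenset(
    {OID_RESULT_PRESENT, OID_RESULT_VALUESET, OID_RESULT_COMPARISON}
)
SUPPORTED_TEMPLATE_OIDS = CRITERION_TEMPLATE_OIDS | RESULT_TEMPLATE_OIDS

#: Datatype display name per criterion template OID.
TEMPLATE_DATATYPES = {
    OID_LAB_RESULT: "Laboratory Test, Result",
    OID_PATIENT_SEX: "Patient Characteristic Sex",
    OID_BIRTH_DATE: "Patient Characteristic Birth Date",
}

_OCCURRENCE_RE = re.compile(r"^Occurrence\s+([A-Z])\s+of\s+(.*)$")
_RESULT_CLAUSE_RE = re.compile(r"\s*\(result[^()]*\)\s*$")


@dataclass(frozen=True)
class CodedConcept:
    """A terminology code with its code system OID."""

    code: str
    code_system: str
    code_system_name: Optional[str] = None
    display_name: Optional[str] = None

    def __post_init__(self):
        if not self.code or not self.code_system:
            raise HqmfParseError("coded concept requires code and codeSystem")


@dataclass(frozen=True)
class ComparisonSpec:
    """A parsed result constraint from a ``...1019.*`` observation."""

    kind: Literal["numeric", "nominal", "present"]
    bound: Literal["high", "low", "both", "none"] = "none"
    value: Optional[float] = None
    unit: Optional[str] = None
    inclusive: bool = False
    nominal_value: Optional[str] = None
    template_oid: str = OID_RESULT_COMPARISON

    def __post_init__(self):
        if self.kind == "numeric" and (self.bound == "none" or self.value is None):
            raise HqmfParseError("numeric comparison requires a bound and a value")
        if self.kind == "nominal" and self.nominal_value is None:
            raise HqmfParseError("nominal comparison requires a nominal value")
        if self.template_oid not in RESULT_TEMPLATE_OIDS:
            raise UnsupportedTemplateError(self.template_oid)


@dataclass(frozen=True)
class HqmfCriterion:
    """One criterion observation extracted from an HQMF document."""

    template_oid: str
    datatype_name: str
    value_set_name: str
    value_set_oid: str
    title: str
    datatype_code: CodedConcept
    status: Optional[str] = None
    comparison: Optional[ComparisonSpec] = None
    occurrence_label: Optional[str] = None
    value_set_display: Optional[str] = None

    def __post_init__(self):
        if self.template_oid not in SUPPORTED_TEMPLATE_OIDS:
            raise UnsupportedTemplateError(self.template_oid)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def split_title(title: str) -> tuple[str, str]:
    """Split a criterion title into (datatype name, value-set name).

    The split is at the *first* colon — datatype names contain commas but
    never colons — and a trailing parenthesized result clause is stripped
    from the value-set name.

    >>> split_title("Laboratory Test, Result: LDL-c (result < 100 mg/dL)")
    ('Laboratory Test, Result', 'LDL-c')
    """
    if ":" not in title:
        raise TitleFormatError(
            f"criterion title has no ':' separator: {title!r}"
        )
    datatype, _, rest = title.partition(":")
    value_set = _RESULT_CLAUSE_RE.sub("", rest).strip()
    datatype = datatype.strip()
    if not datatype or not value_set:
        raise TitleFormatError(f"empty datatype or value-set name in title: {title!r}")
    return datatype, value_set


def _local(elem) -> str:
    return etree.QName(elem).localname


def _find_children(elem, name: str):
    return [c for c in elem if isinstance(c.tag, str) and _local(c) == name]


def _first_child(elem, name: str):
    found = _find_children(elem, name)
    return found[0] if found else None


def extract_comparison(observation) -> ComparisonSpec:
    """Extract a :class:`ComparisonSpec` from a ``...1019.*`` observation.

    For the comparison template the ``IVL_PQ`` value element yields high /
    low / both bounds with per-bound inclusivity; the value-set template
    yields a nominal constraint; the is-present template carries no value.
    """
    template = _first_child(observation, "templateId")
    oid = template.get("root") if template is not None else None
    if oid not in RESULT_TEMPLATE_OIDS:
        raise UnsupportedTemplateError(str(oid))

    if oid == OID_RESULT_PRESENT:
        return ComparisonSpec(kind="present", template_oid=oid)

    value_elem = _first_child(observation, "value")
    if oid == OID_RESULT_VALUESET:
        nominal = None
        if value_elem is not None:
            nominal = value_elem.get("displayName") or value_elem.get("code")
        if nominal is None:
            raise ComparisonFormatError(
                "result/valueset observation lacks a coded value"
            )
        return ComparisonSpec(kind="nominal", nominal_value=nominal, template_oid=oid)

    # numeric comparison: IVL_PQ with high and/or low bound
    if value_elem is None:
        raise ComparisonFormatError("result/comparison observation lacks a value")
    high = _first_child(value_elem, "high")
    low = _first_child(value_elem, "low")
    if high is None and low is None:
        raise ComparisonFormatError(
            "IVL_PQ value carries neither a high nor a low bound"
        )

    def _bound(elem):
        return (
            float(elem.get("value")),
            elem.get("unit"),
            elem.get("inclusive", "true").lower() == "true",
        )

    if high is not None and low is not None:
        hv, hu, hi = _bound(high)
        lv, lu, li = _bound(low)
        return ComparisonSpec(
            kind="numeric", bound="both", value=hv, unit=hu or lu,
            inclusive=hi and li, template_oid=oid,
        )
    elem = high if high is not None else low
    v, u, inc = _bound(elem)
    return ComparisonSpec(
        kind="numeric",
        bound="high" if high is not None else "low",
        value=v,
        unit=u,
        inclusive=inc,
        template_oid=oid,
    )


def _parse_criterion(template_elem) -> HqmfCriterion:
    oid = template_elem.get("root")
    scope = template_elem.getparent()
    datatype_code_elem = _first_child(scope, "code")
    if datatype_code_elem is None:
        raise HqmfParseError(f"criterion for template {oid} lacks a datatype code")
    datatype_code = CodedConcept(
        code=datatype_code_elem.get("code"),
        code_system=datatype_code_elem.get("codeSystem"),
        code_system_name=datatype_code_elem.get("codeSystemName"),
        display_name=datatype_code_elem.get("displayName"),
    )

    inner = None
    for source_of in _find_children(scope, "sourceOf"):
        inner = _first_child(source_of, "observation")
        if inner is not None:
            break
    if inner is None:
        raise HqmfParseError(f"criterion for template {oid} lacks its value-set observation")

    title_elem = _first_child(inner, "title")
    if title_elem is None or not (title_elem.text or "").strip():
        raise TitleFormatError(f"criterion for template {oid} lacks a <title>")
    title = title_elem.text.strip()
    occurrence_label = None
    m = _OCCURRENCE_RE.match(title)
    bare_title = title
    if m:
        occurrence_label, bare_title = m.group(1), m.group(2)
    datatype_name, value_set_name = split_title(bare_title)

    vs_code_elem = _first_child(inner, "code")
    if vs_code_elem is None:
        raise HqmfParseError(f"criterion {title!r} lacks a value-set code")
    value_set_oid = vs_code_elem.get("code")
    value_set_display = vs_code_elem.get("displayName")

    status_elem = _first_child(inner, "statusCode")
    status = status_elem.get("code") if status_elem is not None else None

    comparison = None
    for source_of in _find_children(inner, "sourceOf"):
        result_obs = _first_child(source_of, "observation")
        if result_obs is not None and _first_child(result_obs, "templateId") is not None:
            comparison = extract_comparison(result_obs)
            break

    return HqmfCriterion(
        template_oid=oid,
        datatype_name=datatype_name,
        value_set_name=value_set_name,
        value_set_oid=value_set_oid,
        title=title,
        datatype_code=datatype_code,
        status=status,
        comparison=comparison,
        occurrence_label=occurrence_label,
        value_set_display=value_set_display,
    )


def parse_hqmf_document(xml_text: str | bytes) -> list[HqmfCriterion]:
    """Parse an HQMF R1 document into criterion objects, in document order.

    Nested result-comparison observations are attached to their parent
    criterion, never emitted standalone.  Any templateId outside the
    supported inventory raises :class:`UnsupportedTemplateError` — unknown
    templates are rejected, not skipped.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise HqmfParseError(f"malformed XML: {exc}") from exc

    criteria: list[HqmfCriterion] = []
    for template_elem in root.iter():
        if not isinstance(template_elem.tag, str):
            continue
        if _local(template_elem) != "templateId":
            continue
        oid = template_elem.get("root")
        if oid in CRITERION_TEMPLATE_OIDS:
            criteria.append(_parse_criterion(template_elem))
        elif oid not in RESULT_TEMPLATE_OIDS:
            raise UnsupportedTemplateError(str(oid))
    return criteria


def criteria_to_json(criteria: list[HqmfCriterion]) -> str:
    """Machine-readable dump of parsed criteria for debugging."""
    return json.dumps([asdict(c) for c in criteria], indent=2)
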