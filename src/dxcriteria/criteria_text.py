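"""Textual criterion grammar and HQMF fixture generation.

Quality-measure criteria are often listed in a compact textual form::

    Laboratory Test, Result: INR (result > = 2)
    Occurrence A of Laboratory Test, Result: LDL Code (result < 100 mg/dL)
    Laboratory Test, Result: Hepatitis A Antigen Test (result: 'Seropositive')

This module parses that grammar into :class:`CriterionSpec` objects,
prints them back (inverse printer), renders each criterion as an HQMF R1
XML document structurally matching the standard template shape, and
generates random criteria for property tests.  Value-set OIDs are not part
of the textual form, so rendered documents carry synthetic OIDs derived
deterministically from the value-set name.
"""

from __future__ import annotations

import hashlib
import json
import random
import re
import uuid
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from lxml import etree

from dxcriteria import hqmf_io
from dxcriteria.errors import CriterionSyntaxError, UsageError
from dxcriteria.hqmf_io import (
    OID_RESULT_COMPARISON,
    OID_RESULT_PRESENT,
    OID_RESULT_VALUESET,
    HqmfCriterion,
)

Operator = Literal["lt", "le", "gt", "ge", "eq"]

#: Textual operator token for each operator (printed in the corpus style,
#: with a space inside two-character tokens; the parser accepts both forms).
OPERATOR_TOKENS: dict[Operator, str] = {
    "lt": "<",
    "le": "< =",
    "gt": ">",
    "ge": "> =",
    "eq": "=",
}
_TOKEN_OPERATORS = {"<": "lt", "<=": "le", ">": "gt", ">=": "ge", "=": "eq"}

#: Datatype display name -> criterion template OID (inverse of the parser map).
DATATYPE_TEMPLATE_OIDS = {v: k for k, v in hqmf_io.TEMPLATE_DATATYPES.items()}

#: Datatype-level coded concept rendered for each supported datatype.
_DATATYPE_CODES = {
    "Laboratory Test, Result": ("30954-2", "Results", "2.16.840.1.113883.6.1", None),
    "Patient Characteristic Sex": (
        "263495000", "Gender", "2.16.840.1.113883.6.96", "SNOMED-CT",
    ),
    "Patient Characteristic Birth Date": (
        "21112-8", "Birth date", "2.16.840.1.113883.6.1", None,
    ),
}

#: Code system OID rendered on value-set code elements.
VALUE_SET_CODE_SYSTEM = "2.16.840.1.113883.3.560.101.1"

#: Synthetic value-set OID arc: OIDs under this prefix are generated from
#: the value-set name, not resolved against a terminology service.
SYNTHETIC_OID_ARC = "2.16.840.1.113883.3.560.999"

#: Display unit -> UCUM unit rendered into HQMF ``unit`` attributes.
#: Criterion lists print "copies/mL", but the UCUM encoding of the unit is
#: "[copies]/mL" — the bracketed form that later fails SWRL identifier
#: validation.  The mapping is inverted when recovering the textual form.
UCUM_UNITS = {"copies/mL": "[copies]/mL"}
DISPLAY_UNITS = {v: k for k, v in UCUM_UNITS.items()}

_XSI = "http://www.w3.org/2001/XMLSchema-instance"


@dataclass(frozen=True)
class CriterionSpec:
    """A criterion in the textual grammar."""

    datatype: str
    value_set_name: str
    result_kind: Literal["comparison", "nominal"]
    operator: Optional[Operator] = None
    value: Optional[float] = None
    unit: Optional[str] = None
    nominal_value: Optional[str] = None
    occurrence_label: Optional[str] = None

    def __post_init__(self):
        if self.result_kind == "comparison":
            if self.operator is None or self.value is None:
                raise UsageError("comparison criterion requires operator and value")
        elif self.nominal_value is None or self.operator is not None:
            raise UsageError(
                "nominal criterion requires nominal_value and no operator"
            )


_CRITERION_RE = re.compile(
    r"^(?:Occurrence\s+([A-Z])\s+of\s+)?"  # optional occurrence label
    r"([^:]+):\s*"                          # datatype (no colons)
    r"(.+?)\s*"                             # value-set name (lazy)
    r"\(result(.*)\)\s*$"                   # result clause
)
_COMPARISON_RE = re.compile(
    r"^\s*(<\s*=|>\s*=|<=|>=|<|>|=)\s*([0-9]+(?:\.[0-9]+)?)\s*(.*?)\s*$"
)
_NOMINAL_RE = re.compile(r"^:\s*'([^']*)'\s*$")


def parse_criterion_text(text: str) -> CriterionSpec:
    """Parse one textual criterion line into a :class:`CriterionSpec`.

    Comparison operator tokens are accepted with or without the internal
    space ("> =" == ">=").  The unit is everything between the number and
    the closing parenthesis, trimmed; it may contain spaces ("per mm3") or
    brackets ("[copies]/mL").
    """
    m = _CRITERION_RE.match(text)
    if m is None:
        raise CriterionSyntaxError(
            "criterion does not match '[Occurrence X of ] DATATYPE: NAME (result ...)'",
            text,
        )
    occurrence, datatype, name, clause = m.groups()
    datatype = datatype.strip()
    clause_pos = text.rindex("(result")

    nm = _NOMINAL_RE.match(clause)
    if nm is not None:
        return CriterionSpec(
            datatype=datatype,
            value_set_name=name,
            result_kind="nominal",
            nominal_value=nm.group(1),
            occurrence_label=occurrence,
        )
    cm = _COMPARISON_RE.match(clause)
    if cm is None:
        raise CriterionSyntaxError(
            "result clause is neither \"OP NUM [UNIT]\" nor \": 'TERM'\"",
            text,
            clause_pos,
        )
    token, number, unit = cm.groups()
    op = _TOKEN_OPERATORS[re.sub(r"\s+", "", token)]
    return CriterionSpec(
        datatype=datatype,
        value_set_name=name,
        result_kind="comparison",
        operator=op,  # type: ignore[arg-type]
        value=float(number),
        unit=unit or None,
        occurrence_label=occurrence,
    )


def _fmt_num(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def result_clause(spec: CriterionSpec) -> str:
    """The parenthesized result clause of a criterion, without parens."""
    if spec.result_kind == "nominal":
        return f"result: '{spec.nominal_value}'"
    clause = f"result {OPERATOR_TOKENS[spec.operator]} {_fmt_num(spec.value)}"
    if spec.unit:
        clause += f" {spec.unit}"
    return clause


def format_criterion(spec: CriterionSpec) -> str:
    """Inverse printer: render a spec back to the textual grammar."""
    prefix = f"Occurrence {spec.occurrence_label} of " if spec.occurrence_label else ""
    return f"{prefix}{spec.datatype}: {spec.value_set_name} ({result_clause(spec)})"


def read_criteria_file(text: str) -> list[CriterionSpec]:
    """Parse a plain-text criterion list: one per line, '#' comments."""
    specs = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            specs.append(parse_criterion_text(line))
    return specs


# ---------------------------------------------------------------------------
# HQMF rendering

def synthesize_value_set_oid(value_set_name: str) -> str:
    """Deterministic synthetic OID for a value-set name (sha1-derived arc)."""
    digest = hashlib.sha1(value_set_name.encode("utf-8")).hexdigest()
    return f"{SYNTHETIC_OID_ARC}.{int(digest[:8], 16) % 10**6}"


def _criterion_element(spec: CriterionSpec,
                       result: Optional[tuple] = None) -> etree._Element:
    """Build the outer criterion <observation> element for *spec*.

    *result* overrides the result observation: None derives it from the
    spec; ("present",) emits a result/is-present observation.
    """
    template_oid = DATATYPE_TEMPLATE_OIDS.get(spec.datatype)
    if template_oid is None:
        raise UsageError(
            f"no HQMF template known for datatype {spec.datatype!r}; "
            f"supported: {sorted(DATATYPE_TEMPLATE_OIDS)}"
        )
    code, display, code_system, cs_name = _DATATYPE_CODES[spec.datatype]

    obs = etree.Element("observation", classCode="OBS", moodCode="EVN")
    etree.SubElement(obs, "templateId", root=template_oid)
    stable_id = uuid.uuid5(uuid.NAMESPACE_OID, format_criterion(spec))
    etree.SubElement(obs, "id", root=str(stable_id))
    code_attrs = {"code": code, "displayName": display, "codeSystem": code_system}
    if cs_name:
        code_attrs["codeSystemName"] = cs_name
    etree.SubElement(obs, "code", **code_attrs)

    source_of = etree.SubElement(obs, "sourceOf", typeCode="COMP")
    inner = etree.SubElement(
        source_of, "observation",
        classCode="OBS", moodCode="EVN", isCriterionInd="true",
    )
    etree.SubElement(
        inner, "code",
        code=synthesize_value_set_oid(spec.value_set_name),
        displayName=f"{spec.value_set_name} Value Set",
        codeSystem=VALUE_SET_CODE_SYSTEM,
    )
    title = etree.SubElement(inner, "title")
    title.text = format_criterion(spec) if result is None else (
        f"{spec.datatype}: {spec.value_set_name}"
    )
    etree.SubElement(inner, "statusCode", code="completed")

    refr = etree.SubElement(inner, "sourceOf", typeCode="REFR")
    result_obs = etree.SubElement(
        refr, "observation",
        classCode="OBS", moodCode="EVN", isCriterionInd="true",
    )

    if result == ("present",):
        etree.SubElement(result_obs, "templateId", root=OID_RESULT_PRESENT)
        _result_code(result_obs)
        return obs

    if spec.result_kind == "nominal":
        etree.SubElement(result_obs, "templateId", root=OID_RESULT_VALUESET)
        _result_code(result_obs)
        etree.SubElement(
            result_obs, "value",
            {etree.QName(_XSI, "type"): "CD", "displayName": spec.nominal_value},
        )
        return obs

    etree.SubElement(result_obs, "templateId", root=OID_RESULT_COMPARISON)
    _result_code(result_obs)
    value = etree.SubElement(result_obs, "value", {etree.QName(_XSI, "type"): "IVL_PQ"})
    bounds: list[tuple[str, bool]]
    if spec.operator == "lt":
        bounds = [("high", False)]
    elif spec.operator == "le":
        bounds = [("high", True)]
    elif spec.operator == "gt":
        bounds = [("low", False)]
    elif spec.operator == "ge":
        bounds = [("low", True)]
    else:  # eq: degenerate interval, both bounds inclusive
        bounds = [("low", True), ("high", True)]
    for bound_name, inclusive in bounds:
        attrs = {"value": _fmt_num(spec.value), "inclusive": "true" if inclusive else "false"}
        if spec.unit:
            attrs["unit"] = UCUM_UNITS.get(spec.unit, spec.unit)
        etree.SubElement(value, bound_name, **attrs)
    return obs


def _result_code(result_obs) -> None:
    etree.SubElement(
        result_obs, "code",
        code="385676005", codeSystem="2.16.840.1.113883.6.96",
        displayName="result", codeSystemName="SNOMED-CT",
    )


def _wrap_document(elements: Sequence[etree._Element]) -> str:
    root = etree.Element("QualityMeasureDocument", nsmap={"xsi": _XSI})
    for el in elements:
        root.append(el)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def render_hqmf(spec: CriterionSpec) -> str:
    """Render one criterion as an HQMF R1 XML document.

    ``parse_hqmf_document(render_hqmf(spec))`` recovers the spec:
    lt/le map to a high bound (inclusive false/true), gt/ge to a low bound,
    eq to a degenerate both-bounds interval; nominal results use the
    result/value-set template.
    """
    return _wrap_document([_criterion_element(spec)])


def render_hqmf_document(specs: Sequence[CriterionSpec]) -> str:
    """Render several criteria into a single document, in order."""
    return _wrap_document([_criterion_element(s) for s in specs])


def spec_from_criterion(criterion: HqmfCriterion) -> CriterionSpec:
    """Recover the textual-grammar spec from a parsed HQMF criterion."""
    cmp = criterion.comparison
    common = dict(
        datatype=criterion.datatype_name,
        value_set_name=criterion.value_set_name,
        occurrence_label=criterion.occurrence_label,
    )
    if cmp is None or cmp.kind == "present":
        raise UsageError("criterion has no textual-grammar equivalent (no result)")
    if cmp.kind == "nominal":
        return CriterionSpec(result_kind="nominal", nominal_value=cmp.nominal_value,
                             **common)
    if cmp.bound == "both":
        op: Operator = "eq"
    elif cmp.bound == "high":
        op = "le" if cmp.inclusive else "lt"
    else:
        op = "ge" if cmp.inclusive else "gt"
    unit = DISPLAY_UNITS.get(cmp.unit, cmp.unit) if cmp.unit else None
    return CriterionSpec(
        result_kind="comparison", operator=op, value=cmp.value, unit=unit,
        **common,
    )


# ---------------------------------------------------------------------------
# Random criterion generation

_DEFAULT_NAMES = (
    "INR", "LDL Code", "Neutrophil count", "High Density Lipoprotein HDL",
    "Hemoglobin A1c", "Serum Creatinine", "Prostate Specific Antigen Test",
    "Troponin T", "Viral Load", "Platelet count",
)
_DEFAULT_UNITS = ("mg/dL", "ng/mL", "mmol/L", "per mm3", "copies/mL", "%")
# bracketed UCUM units for the validation-failure path; disjoint from the
# DISPLAY_UNITS values so generated specs round-trip through HQMF verbatim
_BRACKET_UNITS = ("[iU]/L", "m[IU]/L", "[arb'U]/mL")
_DEFAULT_NOMINALS = ("Seropositive", "Positive Finding", "Negative", "Detected")
_OPERATORS: tuple[Operator, ...] = ("lt", "le", "gt", "ge")


def generate_random_criteria(
    n: int,
    seed: int,
    *,
    bracket_unit_prob: float = 0.0,
    nominal_prob: float = 0.3,
    no_unit_prob: float = 0.2,
    occurrence_prob: float = 0.2,
    names: Sequence[str] = _DEFAULT_NAMES,
    units: Sequence[str] = _DEFAULT_UNITS,
    nominal_values: Sequence[str] = _DEFAULT_NOMINALS,
    datatype: str = "Laboratory Test, Result",
) -> list[CriterionSpec]:
    """Generate *n* random criterion specs, deterministic for a given seed.

    Each spec is, with probability ``bracket_unit_prob``, a numeric
    comparison whose unit contains square brackets (the rule-validation
    failure path); otherwise it is nominal with probability
    ``nominal_prob`` and a plain numeric comparison with the rest.
    """
    if n < 0:
        raise UsageError("n must be >= 0")
    rng = random.Random(seed)
    specs = []
    for i in range(n):
        name = f"{rng.choice(list(names))} {i}"
        occurrence = rng.choice("ABC") if rng.random() < occurrence_prob else None
        if rng.random() < bracket_unit_prob:
            specs.append(CriterionSpec(
                datatype=datatype, value_set_name=name, result_kind="comparison",
                operator=rng.choice(_OPERATORS), value=float(rng.randint(1, 500)),
                unit=rng.choice(_BRACKET_UNITS), occurrence_label=occurrence,
            ))
        elif rng.random() < nominal_prob:
            specs.append(CriterionSpec(
                datatype=datatype, value_set_name=name, result_kind="nominal",
                nominal_value=rng.choice(list(nominal_values)),
                occurrence_label=occurrence,
            ))
        else:
            unit = None if rng.random() < no_unit_prob else rng.choice(list(units))
            value = float(rng.randint(1, 500))
            if rng.random() < 0.25:
                value += 0.5
            specs.append(CriterionSpec(
                datatype=datatype, value_set_name=name, result_kind="comparison",
                operator=rng.choice(_OPERATORS), value=value, unit=unit,
                occurrence_label=occurrence,
            ))
    return specs


# ---------------------------------------------------------------------------
# Template fixtures (synthetic documents, one per supported template OID)

def template_fixtures() -> dict[str, str]:
    """One synthetic HQMF document per supported template OID.

    The laboratory and result-comparison shapes follow the published
    template structure; the sex, birth-date, is-present and value-set
    documents are synthetic analogues built on the same skeleton.
    """
    lab = "Laboratory Test, Result"
    fixtures: dict[str, str] = {}
    fixtures[hqmf_io.OID_LAB_RESULT] = render_hqmf(CriterionSpec(
        datatype=lab, value_set_name="LDL-c", result_kind="comparison",
        operator="lt", value=100.0, unit="mg/dL",
    ))
    fixtures[hqmf_io.OID_PATIENT_SEX] = render_hqmf(CriterionSpec(
        datatype="Patient Characteristic Sex", value_set_name="Female",
        result_kind="nominal", nominal_value="Female",
    ))
    fixtures[hqmf_io.OID_BIRTH_DATE] = render_hqmf(CriterionSpec(
        datatype="Patient Characteristic Birth Date", value_set_name="Birthdate",
        result_kind="comparison", operator="ge", value=18.0, unit="a",
    ))
    present_spec = CriterionSpec(
        datatype=lab, value_set_name="Troponin T", result_kind="nominal",
        nominal_value="present",
    )
    fixtures[OID_RESULT_PRESENT] = _wrap_document(
        [_criterion_element(present_spec, result=("present",))]
    )
    fixtures[OID_RESULT_VALUESET] = render_hqmf(CriterionSpec(
        datatype=lab, value_set_name="Hepatitis A Antigen Test",
        result_kind="nominal", nominal_value="Seropositive",
    ))
    fixtures[OID_RESULT_COMPARISON] = render_hqmf(CriterionSpec(
        datatype=lab, value_set_name="INR", result_kind="comparison",
        operator="ge", value=2.0,
    ))
    return fixtures


def write_fixture_set(specs: Sequence[CriterionSpec], out_dir) -> dict:
    """Write one HQMF file per criterion plus a manifest JSON.

    The manifest maps each criterion's text to its file and synthesized
    value-set OID (synthetic: not VSAC-resolved).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"synthetic_value_set_oids": True, "criteria": []}
    for i, spec in enumerate(specs, start=1):
        path = out / f"criterion_{i:03d}.xml"
        path.write_text(render_hqmf(spec), encoding="utf-8")
        manifest["criteria"].append({
            "text": format_criterion(spec),
            "file": path.name,
            "value_set_oid": synthesize_value_set_oid(spec.value_set_name),
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
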