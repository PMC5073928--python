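"""Upper-ontology construction, name sanitization and OWL round trips."""

import pytest
from hypothesis import given, settings, strategies as st
from rdflib import Graph, RDFS, URIRef

import dxcriteria.ontology_core as oc
from dxcriteria import build_dcuo, count_elements, parse_ontology, serialize_ontology
from dxcriteria.errors import InvalidNameError, OntologyError, UsageError
from dxcriteria.ontology_core import (
    AnnotationAssertion,
    ClassDef,
    Identifier,
    IndividualDef,
    Ontology,
    PropertyDef,
    sanitize_name,
)


class TestBuildDcuo:
    def test_element_counts(self, dcuo):
        counts = count_elements(dcuo)
        assert counts.object_properties == 6
        assert counts.data_properties == 1
        assert counts.per_prefix["QDM"] == 10
        assert counts.per_prefix["DCUO"] == 3
        assert counts.root_classes + counts.subclasses == len(dcuo.classes)

    @pytest.mark.parametrize(("datatype", "parent"), [
        ("Laboratory Test, Result", "Investigation Findings"),
        ("Diagnostic Study, Performed", "Investigation Findings"),
        ("Diagnostic, Active", "Title"),
        ("Physical Exam, Performed", "Investigation Findings"),
        ("Symptom, Active", "Signs and Symptoms"),
        ("Medication, Active", "Treatment Properties"),
        ("Patient Characteristic Birth Date", "Specific Condition Properties"),
        ("Patient Characteristic Race", "Specific Condition Properties"),
        ("Patient Characteristic Sex", "Specific Condition Properties"),
        ("Procedure, Recommended", "Treatment Properties"),
    ])
    def test_qdm_datatype_placement(self, dcuo, datatype, parent):
        cls = dcuo.classes[sanitize_name(datatype)]
        assert cls.prefix == "QDM"
        assert cls.parent == sanitize_name(parent)

    def test_manifestation_subelements(self, dcuo):
        for label in ("Investigation Findings", "Signs and Symptoms"):
            cls = dcuo.classes[sanitize_name(label)]
            assert cls.parent == Identifier("Manifestation_Properties")
            assert cls.prefix == "ICD"

    def test_rule_support_classes_are_roots(self, dcuo):
        for name in ("Patient", "Unit", "Evidence"):
            cls = dcuo.classes[Identifier(name)]
            assert cls.prefix == "DCUO" and cls.parent is None

    def test_deterministic_construction(self, dcuo):
        assert build_dcuo() == dcuo


class TestSanitizeName:
    @pytest.mark.parametrize(("raw", "expected"), [
        ("Laboratory Test, Result", "Laboratory_Test,_Result"),
        ("High Density Lipoprotein (HDL)", "High_Density_Lipoprotein_HDL"),
        ("[copies]/mL", "[copies]/mL"),
        ("per mm3", "per_mm3"),
        ("mg/dL", "mg/dL"),
    ])
    def test_examples(self, raw, expected):
        assert sanitize_name(raw) == expected

    def test_empty_raises(self):
        with pytest.raises(InvalidNameError):
            sanitize_name("")
        with pytest.raises(InvalidNameError):
            sanitize_name("   ")

    @settings(max_examples=200, derandomize=True)
    @given(st.text(min_size=1))
    def test_idempotent(self, raw):
        try:
            once = sanitize_name(raw)
        except InvalidNameError:
            return  # names reducing to nothing are rejected, not mangled
        assert sanitize_name(once) == once

    def test_identifier_rejects_whitespace(self):
        with pytest.raises(InvalidNameError):
            Identifier("mg dL")
        with pytest.raises(InvalidNameError):
            Identifier("")


class TestInvariants:
    def test_duplicate_class_rejected(self):
        ont = Ontology()
        ont.add_class(ClassDef(Identifier("A"), "A", "DCUO"))
        with pytest.raises(OntologyError):
            ont.add_class(ClassDef(Identifier("A"), "A again", "DCUO"))

    def test_missing_parent_rejected(self):
        ont = Ontology()
        with pytest.raises(OntologyError):
            ont.add_class(ClassDef(Identifier("B"), "B", "DCUO",
                                   parent=Identifier("missing")))

    def test_subproperty_kind_mismatch_rejected(self):
        ont = Ontology()
        ont.add_property(PropertyDef(Identifier("p"), "object"))
        with pytest.raises(OntologyError):
            ont.add_property(PropertyDef(Identifier("q"), "data",
                                         parent=Identifier("p")))

    def test_individual_requires_existing_class(self):
        ont = Ontology()
        with pytest.raises(OntologyError):
            ont.add_individual(IndividualDef(Identifier("i"),
                                             member_of=Identifier("nope")))

    def test_annotation_requires_existing_subject(self):
        ont = Ontology()
        with pytest.raises(OntologyError):
            ont.annotate(AnnotationAssertion(Identifier("ghost"),
                                             Identifier("code"), "x"))


class TestSerialization:
    @pytest.mark.parametrize("fmt", ["rdfxml", "turtle"])
    def test_dcuo_round_trip(self, dcuo, fmt):
        text = serialize_ontology(dcuo, fmt)
        back = parse_ontology(text, fmt)
        assert back == dcuo
        assert count_elements(back) == count_elements(dcuo)
        for cls in dcuo.classes.values():
            assert back.classes[cls.id].parent == cls.parent

    @pytest.mark.parametrize("fmt", ["rdfxml", "turtle"])
    def test_populated_dcdo_round_trip(self, corpus_dcdo, fmt):
        back = parse_ontology(serialize_ontology(corpus_dcdo, fmt), fmt)
        assert back == corpus_dcdo

    def test_empty_ontology(self):
        ont = Ontology()
        text = serialize_ontology(ont)
        back = parse_ontology(text)
        assert back == ont
        counts = count_elements(back)
        assert counts.root_classes == counts.subclasses == 0
        assert counts.object_properties == counts.data_properties == 0

    def test_unknown_format_raises(self, dcuo):
        with pytest.raises(UsageError):
            serialize_ontology(dcuo, "n3000")
        with pytest.raises(UsageError):
            parse_ontology("", "n3000")

    def test_subclass_axiom_visible_to_independent_rdf_scan(self, corpus_dcdo):
        """The serialized domain ontology carries the value-set subclass
        axiom as a plain RDF triple, checked with rdflib directly."""
        g = Graph()
        g.parse(data=serialize_ontology(corpus_dcdo, "rdfxml"), format="xml")
        ldl = URIRef(oc.NAMESPACES["DCDO"] + "LDL_Code")
        lab = URIRef(oc.NAMESPACES["QDM"] + "Laboratory_Test%2C_Result")
        assert (ldl, RDFS.subClassOf, lab) in g

    def test_serialization_is_byte_stable(self, corpus_dcdo):
        a = serialize_ontology(corpus_dcdo, "rdfxml")
        b = serialize_ontology(corpus_dcdo.copy(), "rdfxml")
        assert a == b
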