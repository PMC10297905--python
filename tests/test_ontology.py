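"""Ontology construction, validation, serialization and the table registry."""

import pytest
from rdflib import Graph, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDFS

from ehrkg.ontology import (
    BASE_IRI,
    ROOT,
    ClassDef,
    DatatypePropertyDef,
    ObjectPropertyDef,
    OntologyFormatError,
    OntologyParseError,
    OntologySchema,
    build_mimic_schema,
    canonical_class,
    parse_ontology,
    serialize_ontology,
    table_registry,
    validate_schema,
)

# The full object-property table: (name, domain set, range).  This is the
# independent statement of the ontology's relational structure the code
# must reproduce.
EXPECTED_OBJECT_PROPERTIES = {
    ("HAS_ADMISSION", frozenset({"Patient"}), "Admission"),
    ("HAS_ICU_STAY", frozenset({"Admission"}), "ICU_Stays"),
    ("HAS_DIAGNOSIS", frozenset({"Admission", "ICU_Stays"}), "ICD_Diagnosis"),
    ("HAS_PROCEDURE", frozenset({"Admission", "ICU_Stays"}), "ICD_Procedure"),
    ("HAS_MEDICATION", frozenset({"Admission", "ICU_Stays"}), "Prescription"),
    ("HAS_LAB_EVENTS", frozenset({"Patient", "Admission", "ICU_Stays"}), "Lab_Event"),
    ("HAS_NOTE", frozenset({"Patient", "Admission", "ICU_Stays"}), "Note_Event"),
    ("HAS_TRANSFER", frozenset({"Admission", "ICU_Stays"}), "Transfers"),
    ("HAS_SERVICE", frozenset({"Admission", "ICU_Stays"}), "Services"),
    ("HAS_LAB_ITEM", frozenset({"Lab_Event"}), "Lab_Item"),
    ("HAS_INDIVIDUAL_ITEM", frozenset({"Prescription", "ICD_Procedure"}), "Individual_Item"),
    ("HAS_CAREGIVER", frozenset({"Patient", "Admission", "ICU_Stays", "ICD_Procedure"}), "CareGivers"),
    ("HAS_CPT_CODE", frozenset({"ICD_Procedure"}), "CPT_Code"),
    ("HAS_DRG_CODE", frozenset({"Admission"}), "DRG_Code"),
    ("HAS_ICU_PROCEDURE_CODE", frozenset({"ICU_Stays"}), "ICD_Procedure_Code"),
    ("HAS_ICU_DIAGNOSIS_CODE", frozenset({"ICU_Stays"}), "ICD_Diagnosis_Code"),
    ("HAS_PATIENT_CARE", frozenset({"Patient"}), "Patient_Care"),
    ("HAS_ICD_DIAGNOSIS", frozenset({"Patient_Care"}), "ICD_Diagnosis"),
    ("HAS_ICD_PROCEDURE", frozenset({"Patient_Care"}), "ICD_Procedure"),
}


class TestBuiltinSchema:
    def test_object_property_fidelity(self, schema):
        got = {(p.name, frozenset(p.domains), p.range)
               for p in schema.object_properties}
        assert got == EXPECTED_OBJECT_PROPERTIES
        assert len(schema.object_properties) == 19

    def test_has_admission_lookup(self, schema):
        p = schema.object_property("HAS_ADMISSION")
        assert set(p.domains) == {"Patient"}
        assert p.range == "Admission"
        assert p.source_table == "admissions.csv"

    def test_union_domain_medication(self, schema):
        p = schema.object_property("HAS_MEDICATION")
        assert set(p.domains) == {"Admission", "ICU_Stays"}

    def test_event_subclass_ancestry(self, schema):
        assert schema.ancestors("Chart_Event") == ["Events", ROOT]
        for sub in ("CPT_Event", "Input_Event", "Lab_Event",
                    "Microbiology_Event", "Note_Event", "Output_Event"):
            assert schema.class_map()[sub].parent == "Events"

    def test_patient_care_and_codes_branches(self, schema):
        cmap = schema.class_map()
        assert cmap["ICD_Diagnosis"].parent == "Patient_Care"
        assert cmap["ICD_Procedure"].parent == "Patient_Care"
        for sub in ("CPT_Code", "DRG_Code", "ICD_Diagnosis_Code",
                    "ICD_Procedure_Code"):
            assert cmap[sub].parent == "Codes"

    def test_base_iri_and_prefix(self, schema):
        assert schema.base_iri == "http://mimicIII.com/base/"
        assert schema.prefix == "mc"

    def test_alias_map_reconciles_printed_labels(self):
        assert canonical_class("Diagnosis") == "ICD_Diagnosis"
        assert canonical_class("Lab_Items") == "Lab_Item"
        assert canonical_class("Individual Item") == "Individual_Item"
        assert canonical_class("ICU Diagnosis Code") == "ICD_Diagnosis_Code"
        assert canonical_class("patient.csv") == "patients.csv"

    def test_domain_range_closure(self, schema):
        declared = {c.name for c in schema.classes}
        for p in schema.object_properties:
            assert set(p.domains) <= declared
            assert p.range in declared
        for p in schema.datatype_properties:
            assert set(p.domains) <= declared

    def test_property_namespaces_disjoint(self, schema):
        obj = {p.name for p in schema.object_properties}
        dt = {p.name for p in schema.datatype_properties}
        assert not obj & dt


class TestValidation:
    def test_builtin_schema_clean(self, schema):
        assert validate_schema(schema) == []

    def test_cycle_detected(self):
        s = OntologySchema(
            classes=(ClassDef("A", "B"), ClassDef("B", "A")),
            object_properties=(), datatype_properties=())
        issues = validate_schema(s)
        assert [i.code for i in issues] == ["CYCLE"]

    def test_undeclared_range(self, schema):
        bad = ObjectPropertyDef("HAS_X", ("Patient",), "Diagnosi", "x.csv")
        s = OntologySchema(
            classes=schema.classes,
            object_properties=schema.object_properties + (bad,),
            datatype_properties=())
        issues = validate_schema(s)
        assert [i.code for i in issues] == ["UNDECLARED_CLASS"]
        assert issues[0].subject == "HAS_X"

    def test_duplicate_class_name(self, schema):
        s = OntologySchema(
            classes=schema.classes + (ClassDef("Patient"),),
            object_properties=(), datatype_properties=())
        assert "DUPLICATE_NAME" in [i.code for i in validate_schema(s)]


class TestSerialization:
    @pytest.mark.parametrize("fmt", ["turtle", "rdfxml"])
    def test_round_trip(self, schema, fmt):
        doc = serialize_ontology(schema, fmt)
        assert parse_ontology(doc, fmt) == schema

    def test_prefix_binding_in_turtle(self, schema):
        doc = serialize_ontology(schema, "turtle")
        assert "@prefix mc: <http://mimicIII.com/base/>" in doc

    def test_union_domain_structurally_present(self, schema):
        g = Graph()
        g.parse(data=serialize_ontology(schema, "turtle"), format="turtle")
        dom = g.value(URIRef(BASE_IRI + "HAS_MEDICATION"), RDFS.domain)
        members = set(Collection(g, g.value(dom, OWL.unionOf)))
        assert members == {URIRef(BASE_IRI + "Admission"),
                           URIRef(BASE_IRI + "ICU_Stays")}

    def test_deterministic_output(self, schema):
        assert serialize_ontology(schema, "turtle") == \
            serialize_ontology(schema, "turtle")

    def test_truncated_document_raises(self, schema):
        doc = serialize_ontology(schema, "turtle")
        with pytest.raises(OntologyParseError):
            parse_ontology(doc[: len(doc) // 2], "turtle")

    def test_unsupported_format(self, schema):
        with pytest.raises(OntologyFormatError):
            serialize_ontology(schema, "n3000")


class TestRegistry:
    def test_twenty_six_files(self):
        assert len(table_registry()) == 26

    def test_names_distinct_uppercase(self):
        names = [t.file_name for t in table_registry()]
        assert len(set(names)) == 26
        assert all(n == n.upper() for n in names)

    def test_patients_entry(self):
        by_name = {t.file_name: t for t in table_registry()}
        assert by_name["PATIENTS"].primary_key == ("SUBJECT_ID",)
        assert "GENDER" in by_name["PATIENTS"].column_names()

    def test_core_tables_fully_columned(self):
        by_name = {t.file_name: t for t in table_registry()}
        for name in ("ADMISSIONS", "ICUSTAYS", "DIAGNOSES_ICD", "PRESCRIPTIONS"):
            assert len(by_name[name].columns) >= 5

    def test_primary_keys_exist_and_non_nullable(self):
        for t in table_registry():
            cols = {c.name: c for c in t.columns}
            for k in t.primary_key:
                assert k in cols and not cols[k].nullable
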