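"""IRI minting, literal typing, row/table/dataset mapping, conformance."""

import io

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrkg.mappings import default_mapping, default_mappings
from ehrkg.ontology import BASE_IRI
from ehrkg.rdf_mapping import (
    ABSENT,
    RDF_TYPE,
    ColumnRule,
    CsvSchemaError,
    DatasetError,
    Iri,
    LinkRule,
    LiteralCoercionError,
    MintingError,
    TableMapping,
    Triple,
    TripleGraph,
    TypedLiteral,
    UnmappedValue,
    categorical_resource,
    make_literal,
    map_dataset,
    map_row,
    map_table,
    mint_iri,
    parse_graph,
    parse_iri,
    serialize_graph,
    validate_graph,
)


class TestMinting:
    def test_patient_example(self):
        assert mint_iri("Patient", ["12345"]).value == \
            "http://mimicIII.com/base/Patient/12345"

    def test_deterministic(self):
        assert mint_iri("Patient", ["7"]) == mint_iri("Patient", ["7"])

    def test_composite_key_joined_with_hyphen(self):
        iri = mint_iri("Lab_Event", ["12345", "50912"])
        assert iri.value.endswith("Lab_Event/12345-50912")

    def test_empty_key_rejected(self):
        with pytest.raises(MintingError):
            mint_iri("Patient", [" "])
        with pytest.raises(MintingError):
            mint_iri("Patient", [])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.text(min_size=1, max_size=12).filter(lambda s: s.strip()),
                    min_size=1, max_size=3))
    def test_mint_parse_inverse(self, keys):
        """Minted IRIs parse back to (class, keys) even with reserved chars."""
        cls, parsed = parse_iri(mint_iri("Lab_Event", keys))
        assert cls == "Lab_Event"
        assert parsed == [k.strip() for k in keys]


class TestLiterals:
    @pytest.mark.parametrize("raw", ["", "   ", "NULL", "null"])
    def test_null_sentinels_absent(self, raw):
        assert make_literal(raw, "string") is ABSENT

    def test_code_stays_string(self):
        lit = make_literal("41401", "code")
        assert lit == TypedLiteral("41401", "string")
        assert lit.xsd_type is None

    def test_datetime_normalized_to_iso(self):
        assert make_literal("2101-10-20 19:08:00", "datetime").lexical == \
            "2101-10-20T19:08:00"

    def test_bare_date_padded(self):
        assert make_literal("2101-10-20", "datetime").lexical == \
            "2101-10-20T00:00:00"

    @pytest.mark.parametrize("raw,lt", [("abc", "integer"), ("1.2.3", "decimal"),
                                        ("someday", "datetime")])
    def test_coercion_errors(self, raw, lt):
        with pytest.raises(LiteralCoercionError):
            make_literal(raw, lt)


class TestCategorical:
    @pytest.mark.parametrize("prop,raw,local", [
        ("gender", "M", "Male"),
        ("marital_status", "MARRIED", "Married"),
        ("race", "WHITE", "White"),
    ])
    def test_vocabulary(self, prop, raw, local):
        assert categorical_resource(prop, raw).value == BASE_IRI + local

    def test_outside_vocabulary(self):
        with pytest.raises(UnmappedValue):
            categorical_resource("gender", "ZZZ")


@pytest.fixture
def patients_mini_mapping():
    return TableMapping(
        table_name="PATIENTS",
        subject_class="Patient",
        subject_key_columns=("SUBJECT_ID",),
        column_rules=(
            ColumnRule("SUBJECT_ID", "subject_id", "integer"),
            ColumnRule("GENDER", "gender", "categorical"),
            ColumnRule("DOB", "dob", "datetime"),
        ),
    )


class TestMapRow:
    def test_patients_row_exact_triples(self, schema, patients_mini_mapping):
        """Hand-enumerated star for one PATIENTS row (key echo on)."""
        row = {"SUBJECT_ID": "12345", "GENDER": "M", "DOB": "2050-01-01 00:00:00"}
        triples = set(map_row(patients_mini_mapping, row, schema))
        s = Iri(BASE_IRI + "Patient/12345")
        assert triples == {
            Triple(s, Iri(RDF_TYPE), Iri(BASE_IRI + "Patient")),
            Triple(s, Iri(BASE_IRI + "subject_id"), TypedLiteral("12345", "integer")),
            Triple(s, Iri(BASE_IRI + "gender"), Iri(BASE_IRI + "Male")),
            Triple(s, Iri(BASE_IRI + "dob"), TypedLiteral("2050-01-01T00:00:00", "datetime")),
        }

    def test_admissions_link_triple(self, schema):
        mapping = default_mapping("ADMISSIONS")
        row = {c: "" for c in ("ROW_ID", "ADMISSION_TYPE", "ADMISSION_LOCATION",
                               "INSURANCE", "DIAGNOSIS", "HOSPITAL_EXPIRE_FLAG")}
        row |= {"SUBJECT_ID": "10", "HADM_ID": "100",
                "ADMITTIME": "2101-01-01 00:00:00", "DISCHTIME": "2101-01-05 00:00:00"}
        triples = set(map_row(mapping, row, schema))
        assert Triple(Iri(BASE_IRI + "Patient/10"),
                      Iri(BASE_IRI + "HAS_ADMISSION"),
                      Iri(BASE_IRI + "Admission/100")) in triples

    def test_prescription_union_domain_resolution(self, schema):
        """HADM_ID only -> one medication link from the Admission; both
        context keys -> links from both the admission and the ICU stay."""
        mapping = default_mapping("PRESCRIPTIONS")
        base_row = {c: "" for c in ("STARTDATE", "ENDDATE", "DRUG_TYPE", "DRUG",
                                    "DOSE_VAL_RX", "DOSE_UNIT_RX", "ROUTE")}
        row = base_row | {"ROW_ID": "1", "SUBJECT_ID": "10", "HADM_ID": "100",
                          "ICUSTAY_ID": ""}
        med = Iri(BASE_IRI + "HAS_MEDICATION")
        links = [t for t in map_row(mapping, row, schema) if t.predicate == med]
        assert links == [Triple(Iri(BASE_IRI + "Admission/100"), med,
                                Iri(BASE_IRI + "Prescription/1"))]
        row["ICUSTAY_ID"] = "200"
        links = {t.subject.value for t in map_row(mapping, row, schema)
                 if t.predicate == med}
        assert links == {BASE_IRI + "Admission/100", BASE_IRI + "ICU_Stays/200"}

    def test_missing_key_raises(self, schema, patients_mini_mapping):
        from ehrkg.rdf_mapping import RowError
        with pytest.raises(RowError):
            map_row(patients_mini_mapping, {"SUBJECT_ID": "", "GENDER": "M"}, schema)


class TestMapTable:
    def _csv(self, text: str):
        return io.StringIO(text)

    def test_header_only_empty_graph(self, schema):
        src = self._csv("ROW_ID,ICD9_CODE,SHORT_TITLE,LONG_TITLE\n")
        graph, report = map_table(default_mapping("D_ICD_DIAGNOSES"), src, schema)
        assert len(graph) == 0 and report.rows_read == 0

    def test_conservation_formula(self, schema):
        """R fully-populated rows, C column rules, L resolvable links
        -> exactly R*(1+C+L) triples (no duplicates present)."""
        src = self._csv(
            "ROW_ID,SUBJECT_ID,HADM_ID,SEQ_NUM,ICD9_CODE\n"
            "1,10,100,1,486\n2,10,100,2,4280\n3,11,101,1,25000\n")
        mapping = default_mapping("DIAGNOSES_ICD")
        graph, report = map_table(mapping, src, schema)
        R, C, L = 3, len(mapping.column_rules), len(mapping.link_rules)
        assert len(graph) == R * (1 + C + L)
        assert report.rows_read == 3 and report.triples_emitted == len(graph)

    def test_duplicate_row_counted_once(self, schema):
        one = "1,10,100,1,486\n"
        g1, _ = map_table(default_mapping("DIAGNOSES_ICD"), self._csv(
            "ROW_ID,SUBJECT_ID,HADM_ID,SEQ_NUM,ICD9_CODE\n" + one), schema)
        g2, _ = map_table(default_mapping("DIAGNOSES_ICD"), self._csv(
            "ROW_ID,SUBJECT_ID,HADM_ID,SEQ_NUM,ICD9_CODE\n" + one + one), schema)
        assert g1 == g2

    def test_header_mismatch(self, schema):
        src = self._csv("ROW_ID,WRONG\n1,x\n")
        with pytest.raises(CsvSchemaError, match="missing"):
            map_table(default_mapping("D_ICD_DIAGNOSES"), src, schema)

    def test_coercion_recorded_not_fatal(self, schema):
        src = self._csv(
            "ROW_ID,SUBJECT_ID,HADM_ID,SEQ_NUM,ICD9_CODE\n1,10,100,abc,486\n")
        graph, report = map_table(default_mapping("DIAGNOSES_ICD"), src, schema)
        assert [w.code for w in report.warnings] == ["COERCION"]
        assert report.rows_read == 1 and len(graph) > 0


class TestMapDataset:
    def test_missing_required_table(self, tmp_path, schema):
        with pytest.raises(DatasetError, match="PATIENTS"):
            map_dataset(tmp_path, schema, default_mappings())

    def test_all_predicates_declared(self, mapped, schema):
        graph, _ = mapped
        declared = {BASE_IRI + p.name for p in schema.object_properties} | \
                   {BASE_IRI + p.name for p in schema.datatype_properties}
        for t in graph:
            assert t.predicate.value == RDF_TYPE or t.predicate.value in declared

    def test_idempotent(self, small_dataset, schema, mapped):
        path, _ = small_dataset
        graph2, _ = map_dataset(path, schema, default_mappings())
        assert graph2 == mapped[0]

    def test_minted_iris_invert(self, mapped, schema):
        graph, _ = mapped
        classes = {c.name for c in schema.classes}
        seen = 0
        for t in graph:
            if t.predicate.value == RDF_TYPE:
                cls, keys = parse_iri(t.subject)
                assert cls in classes and keys
                seen += 1
        assert seen > 0


class TestValidateGraph:
    def test_mapped_synthetic_clean(self, mapped, schema):
        graph, _ = mapped
        assert validate_graph(graph, schema).ok

    def test_injected_domain_violation(self, schema):
        g = TripleGraph([
            Triple(Iri(BASE_IRI + "Prescription/1"), Iri(RDF_TYPE),
                   Iri(BASE_IRI + "Prescription")),
            Triple(Iri(BASE_IRI + "Admission/1"), Iri(RDF_TYPE),
                   Iri(BASE_IRI + "Admission")),
            Triple(Iri(BASE_IRI + "Prescription/1"), Iri(BASE_IRI + "HAS_ADMISSION"),
                   Iri(BASE_IRI + "Admission/1")),
        ])
        report = validate_graph(g, schema)
        assert report.codes() == ["DOMAIN_VIOLATION"]

    def test_union_domain_icu_subject_allowed(self, schema):
        g = TripleGraph([
            Triple(Iri(BASE_IRI + "ICU_Stays/5"), Iri(RDF_TYPE),
                   Iri(BASE_IRI + "ICU_Stays")),
            Triple(Iri(BASE_IRI + "Prescription/9"), Iri(RDF_TYPE),
                   Iri(BASE_IRI + "Prescription")),
            Triple(Iri(BASE_IRI + "ICU_Stays/5"), Iri(BASE_IRI + "HAS_MEDICATION"),
                   Iri(BASE_IRI + "Prescription/9")),
        ])
        assert validate_graph(g, schema).ok

    def test_undeclared_predicate(self, schema):
        g = TripleGraph([
            Triple(Iri(BASE_IRI + "Patient/1"), Iri(BASE_IRI + "HAS_WINGS"),
                   Iri(BASE_IRI + "Patient/2")),
        ])
        assert validate_graph(g, schema).codes() == ["UNDECLARED_PREDICATE"]

    def test_subclass_aware_range(self, schema):
        # HAS_PATIENT_CARE ranges over Patient_Care; an ICD_Diagnosis
        # object is a subclass member and must conform.
        g = TripleGraph([
            Triple(Iri(BASE_IRI + "Patient/1"), Iri(RDF_TYPE),
                   Iri(BASE_IRI + "Patient")),
            Triple(Iri(BASE_IRI + "ICD_Diagnosis/3"), Iri(RDF_TYPE),
                   Iri(BASE_IRI + "ICD_Diagnosis")),
            Triple(Iri(BASE_IRI + "Patient/1"), Iri(BASE_IRI + "HAS_PATIENT_CARE"),
                   Iri(BASE_IRI + "ICD_Diagnosis/3")),
        ])
        assert validate_graph(g, schema).ok


class TestGraphSerialization:
    def test_round_trip_and_byte_stability(self, mapped):
        graph, _ = mapped
        nt = serialize_graph(graph, "ntriples")
        back = parse_graph(nt, "ntriples")
        assert back == graph
        assert serialize_graph(back, "ntriples") == nt

    def test_sorted_lines(self, mapped):
        nt = serialize_graph(mapped[0], "ntriples")
        lines = nt.splitlines()
        assert lines == sorted(lines)

    def test_empty_graph(self):
        assert serialize_graph(TripleGraph(), "ntriples") == ""

    def test_turtle_round_trip(self, mapped):
        ttl = serialize_graph(mapped[0], "turtle")
        assert parse_graph(ttl, "turtle") == mapped[0]

    def test_parse_error(self):
        from ehrkg.rdf_mapping import GraphParseError
        with pytest.raises(GraphParseError):
            parse_graph("<a> <b> malformed", "ntriples")


class TestConservationInvariant:
    def test_against_independent_row_scan(self, small_dataset, schema):
        """Per-table triple counts equal the brute-force formula
        sum_rows(1 + non-null mapped columns + resolvable links),
        recomputed here with pandas, independent of the mapper."""
        path, _ = small_dataset
        for name, mapping in default_mappings().items():
            df = pd.read_csv(path / f"{name}.csv", dtype=str, keep_default_na=False)
            expected = 0
            for _, row in df.iterrows():
                nonnull_cols = sum(
                    1 for r in mapping.column_rules
                    if row[r.column].strip() not in ("",) and
                    row[r.column].strip().lower() != "null")
                links = sum(
                    1 for lr in mapping.link_rules
                    if all(row[c].strip() not in ("",) and
                           row[c].strip().lower() != "null" for c in lr.columns))
                expected += 1 + nonnull_cols + links
            graph, report = map_table(mapping, path / f"{name}.csv", schema)
            assert len(graph) == expected, name
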