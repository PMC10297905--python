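"""EHR ontology for MIMIC-III-shaped critical-care records.

The ontology models an ICU electronic-health-record database as OWL
classes (Patient, Admission, ICU_Stays, diagnosis/procedure records,
events, code dictionaries ...) connected by object properties such as
``HAS_ADMISSION`` and ``HAS_DIAGNOSIS``.  Several object properties have
a *union domain*: a medication, for example, may hang off either an
admission or an ICU stay, so ``HAS_MEDICATION`` declares both classes as
its domain and the serializer emits an ``owl:unionOf`` construct.

The module also carries the registry of the 26 MIMIC-III v1.4 CSV files
(:func:`table_registry`), which the mapping and synthetic-data layers
share as their single source of truth for file names, columns and keys.

Demographics note: gender, race and marital status are modelled as
Patient-level datatype properties (and generated into PATIENTS.csv),
although the real MIMIC-III distribution stores ethnicity and marital
status per admission.  The cohort queries this package reproduces filter
demographics on the patient, so the patient-level placement is kept and
documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS, XSD

#: Marker used as the parent of top-level classes (stands for owl:Thing).
ROOT = "ROOT"

BASE_IRI = "http://mimicIII.com/base/"
PREFIX = "mc"

MC = Namespace(BASE_IRI)

#: Literal types understood by the mapping layer.
LITERAL_TYPES = ("string", "integer", "decimal", "datetime", "code", "categorical")

_XSD_FOR_TYPE = {
    "string": XSD.string,
    "integer": XSD.integer,
    "decimal": XSD.decimal,
    "datetime": XSD.dateTime,
    "code": XSD.string,
    "categorical": XSD.string,
}


@dataclass(frozen=True)
class ClassDef:
    """One ontology class: its canonical name, parent and source files."""

    name: str
    parent: str = ROOT
    description: str = ""
    source_tables: tuple[str, ...] = ()


@dataclass(frozen=True)
class ObjectPropertyDef:
    """An object property with a (possibly union) domain and a range."""

    name: str
    domains: tuple[str, ...]
    range: str
    source_table: str


@dataclass(frozen=True)
class DatatypePropertyDef:
    """A datatype property: lowercased column name attached to classes.

    ``domains`` is a tuple because the same column name (e.g.
    ``subject_id``, ``icd9_code``) legitimately appears on several
    tables; the property is one IRI with a union domain.
    """

    name: str
    domains: tuple[str, ...]
    literal_type: str
    sources: tuple[str, ...]


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    subject: str
    message: str


@dataclass(frozen=True)
class OntologySchema:
    classes: tuple[ClassDef, ...]
    object_properties: tuple[ObjectPropertyDef, ...]
    datatype_properties: tuple[DatatypePropertyDef, ...]
    base_iri: str = BASE_IRI
    prefix: str = PREFIX

    # -- lookup helpers -------------------------------------------------
    def class_map(self) -> dict[str, ClassDef]:
        return {c.name: c for c in self.classes}

    def object_property(self, name: str) -> ObjectPropertyDef:
        for p in self.object_properties:
            if p.name == name:
                return p
        raise KeyError(name)

    def datatype_property(self, name: str) -> DatatypePropertyDef:
        for p in self.datatype_properties:
            if p.name == name:
                return p
        raise KeyError(name)

    def has_class(self, name: str) -> bool:
        return any(c.name == name for c in self.classes)

    def ancestors(self, name: str) -> list[str]:
        """Chain of parents from ``name`` (exclusive) up to ROOT (inclusive)."""
        cmap = self.class_map()
        out: list[str] = []
        cur = cmap[name].parent
        seen = {name}
        while cur != ROOT:
            if cur in seen or cur not in cmap:
                break  # cycle or dangling parent; validation reports it
            out.append(cur)
            seen.add(cur)
            cur = cmap[cur].parent
        out.append(ROOT)
        return out

    def descendants(self, name: str) -> set[str]:
        """All classes at or below ``name`` in the subclass DAG."""
        children: dict[str, list[str]] = {}
        for c in self.classes:
            children.setdefault(c.parent, []).append(c.name)
        out: set[str] = set()
        stack = [name]
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            stack.extend(children.get(cur, []))
        return out

    def iri(self, local: str) -> URIRef:
        return URIRef(self.base_iri + local)


# ---------------------------------------------------------------------------
# Built-in MIMIC-III schema
# ---------------------------------------------------------------------------

# Range/domain labels are written inconsistently across the source
# material ("Diagnosis", "Lab_Items", "Individual Item", "ICU Diagnosis
# Code", "patient.csv" ...).  This alias map reconciles every label to
# a canonical class identifier and is test-covered.
CLASS_ALIASES: dict[str, str] = {
    "Diagnosis": "ICD_Diagnosis",
    "Procedure": "ICD_Procedure",
    "Medication": "Prescription",
    "Lab_Events": "Lab_Event",
    "Note_Events": "Note_Event",
    "Transfer": "Transfers",
    "Service": "Services",
    "Lab_Items": "Lab_Item",
    "Individual Item": "Individual_Item",
    "Caregiver": "CareGivers",
    "CPT Code": "CPT_Code",
    "DRG Code": "DRG_Code",
    "ICU Procedure": "ICD_Procedure_Code",
    "ICU Diagnosis Code": "ICD_Diagnosis_Code",
    "Patient Care": "Patient_Care",
    "ICD Diagnosis": "ICD_Diagnosis",
    "ICD Procedure": "ICD_Procedure",
    "ICU_Stay": "ICU_Stays",
    # "patient.csv" in the property table is read as the PATIENTS file.
    "patient.csv": "patients.csv",
}


def canonical_class(label: str) -> str:
    return CLASS_ALIASES.get(label, label)


_CLASSES: tuple[ClassDef, ...] = (
    ClassDef("Patient", ROOT, "Patient demographics: gender, race, marital status, dates of birth and death", ("PATIENTS.csv",)),
    ClassDef("Admission", ROOT, "Hospital admission with admit/discharge times and admission details", ("ADMISSIONS.csv",)),
    ClassDef("CareGivers", ROOT, "Caregivers responsible for patient care", ("CAREGIVERS.csv",)),
    ClassDef("ICU_Stays", ROOT, "ICU stay with in/out times, length of stay and care unit", ("ICUSTAYS.csv",)),
    ClassDef("Transfers", ROOT, "Patient transfers between hospital locations", ("TRANSFERS.csv",)),
    ClassDef("Services", ROOT, "Hospital services provided during an admission", ("SERVICES.csv",)),
    ClassDef("Prescription", ROOT, "Medications prescribed to patients", ("PRESCRIPTIONS.csv",)),
    ClassDef("Callout", ROOT, "Patient requests for consultations / discharge callouts", ("CALLOUT.csv",)),
    # Patient_Care branch: coded clinical records attached to a patient.
    ClassDef("Patient_Care", ROOT, "Coded records of surgeries, interventions and conditions", ()),
    ClassDef("ICD_Diagnosis", "Patient_Care", "ICD-9 coded diagnosis assigned during an admission", ("DIAGNOSES_ICD.csv",)),
    ClassDef("ICD_Procedure", "Patient_Care", "ICD-9 coded procedure performed during an admission", ("PROCEDURES_ICD.csv",)),
    # Codes branch: dictionaries describing the code systems.
    ClassDef("Codes", ROOT, "Dictionary entries describing clinical codes", ()),
    ClassDef("CPT_Code", "Codes", "Current Procedural Terminology code dictionary entry", ("D_CPT.csv",)),
    ClassDef("DRG_Code", "Codes", "Diagnosis-related-group code dictionary entry", ("DRGCODES.csv",)),
    ClassDef("ICD_Diagnosis_Code", "Codes", "ICD-9 diagnosis code dictionary entry", ("D_ICD_DIAGNOSES.csv",)),
    ClassDef("ICD_Procedure_Code", "Codes", "ICD-9 procedure code dictionary entry", ("D_ICD_PROCEDURES.csv",)),
    ClassDef("Lab_Item", "Codes", "Laboratory measurement dictionary entry", ("D_LABITEMS.csv",)),
    ClassDef("Individual_Item", "Codes", "Charted item dictionary entry", ("D_ITEMS.csv",)),
    # Events branch.
    ClassDef("Events", ROOT, "Clinical and procedural events and observations", ()),
    ClassDef("Chart_Event", "Events", "Charted observation", ("CHARTEVENTS.csv",)),
    ClassDef("CPT_Event", "Events", "Billed CPT event", ("CPTEVENTS.csv",)),
    ClassDef("Input_Event", "Events", "Fluid/medication input event", ("INPUTEVENTS_CV.csv", "INPUTEVENTS_MV.csv")),
    ClassDef("Lab_Event", "Events", "Laboratory measurement event", ("LABEVENTS.csv",)),
    ClassDef("Microbiology_Event", "Events", "Microbiology culture event", ("MICROBIOLOGYEVENTS.csv",)),
    ClassDef("Note_Event", "Events", "Free-text clinical note", ("NOTEEVENTS.csv",)),
    ClassDef("Output_Event", "Events", "Fluid output event", ("OUTPUTEVENTS.csv",)),
)

# The 19 object properties: (name, domains, range, source file).
_OBJECT_PROPERTIES: tuple[ObjectPropertyDef, ...] = (
    ObjectPropertyDef("HAS_ADMISSION", ("Patient",), "Admission", "admissions.csv"),
    ObjectPropertyDef("HAS_ICU_STAY", ("Admission",), "ICU_Stays", "icustays.csv"),
    ObjectPropertyDef("HAS_DIAGNOSIS", ("Admission", "ICU_Stays"), "ICD_Diagnosis", "diagnoses_icd.csv"),
    ObjectPropertyDef("HAS_PROCEDURE", ("Admission", "ICU_Stays"), "ICD_Procedure", "procedures_icd.csv"),
    ObjectPropertyDef("HAS_MEDICATION", ("Admission", "ICU_Stays"), "Prescription", "prescriptions.csv"),
    ObjectPropertyDef("HAS_LAB_EVENTS", ("Patient", "Admission", "ICU_Stays"), "Lab_Event", "labevents.csv"),
    ObjectPropertyDef("HAS_NOTE", ("Patient", "Admission", "ICU_Stays"), "Note_Event", "noteevents.csv"),
    ObjectPropertyDef("HAS_TRANSFER", ("Admission", "ICU_Stays"), "Transfers", "transfers.csv"),
    ObjectPropertyDef("HAS_SERVICE", ("Admission", "ICU_Stays"), "Services", "services.csv"),
    ObjectPropertyDef("HAS_LAB_ITEM", ("Lab_Event",), "Lab_Item", "d_labitems.csv"),
    ObjectPropertyDef("HAS_INDIVIDUAL_ITEM", ("Prescription", "ICD_Procedure"), "Individual_Item", "d_items.csv"),
    ObjectPropertyDef("HAS_CAREGIVER", ("Patient", "Admission", "ICU_Stays", "ICD_Procedure"), "CareGivers", "caregivers.csv"),
    ObjectPropertyDef("HAS_CPT_CODE", ("ICD_Procedure",), "CPT_Code", "d_cpt.csv"),
    ObjectPropertyDef("HAS_DRG_CODE", ("Admission",), "DRG_Code", "drgcodes.csv"),
    ObjectPropertyDef("HAS_ICU_PROCEDURE_CODE", ("ICU_Stays",), "ICD_Procedure_Code", "d_icd_procedures.csv"),
    ObjectPropertyDef("HAS_ICU_DIAGNOSIS_CODE", ("ICU_Stays",), "ICD_Diagnosis_Code", "d_icd_diagnoses.csv"),
    ObjectPropertyDef("HAS_PATIENT_CARE", ("Patient",), "Patient_Care", "patients.csv"),
    ObjectPropertyDef("HAS_ICD_DIAGNOSIS", ("Patient_Care",), "ICD_Diagnosis", "diagnoses_icd.csv"),
    ObjectPropertyDef("HAS_ICD_PROCEDURE", ("Patient_Care",), "ICD_Procedure", "procedures_icd.csv"),
)


# ---------------------------------------------------------------------------
# Table registry: the 26 MIMIC-III v1.4 CSV files
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnSchema:
    name: str
    literal_type: str
    nullable: bool = False


@dataclass(frozen=True)
class ForeignKey:
    column: str
    referenced_table: str
    referenced_column: str


@dataclass(frozen=True)
class TableSchema:
    file_name: str
    columns: tuple[ColumnSchema, ...]
    primary_key: tuple[str, ...]
    foreign_keys: tuple[ForeignKey, ...] = ()

    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]


def _cols(*specs: tuple) -> tuple[ColumnSchema, ...]:
    return tuple(ColumnSchema(*s) for s in specs)


_FK_PAT = ForeignKey("SUBJECT_ID", "PATIENTS", "SUBJECT_ID")
_FK_ADM = ForeignKey("HADM_ID", "ADMISSIONS", "HADM_ID")
_FK_ICU = ForeignKey("ICUSTAY_ID", "ICUSTAYS", "ICUSTAY_ID")

# Core tables carry full column lists; the rest are name + key only.
_CORE_TABLES: tuple[TableSchema, ...] = (
    TableSchema(
        "PATIENTS",
        _cols(("ROW_ID", "integer"), ("SUBJECT_ID", "integer"),
              ("GENDER", "categorical"), ("RACE", "categorical"),
              ("MARITAL_STATUS", "categorical"),
              ("DOB", "datetime"), ("DOD", "datetime", True),
              ("EXPIRE_FLAG", "integer")),
        ("SUBJECT_ID",),
    ),
    TableSchema(
        "ADMISSIONS",
        _cols(("ROW_ID", "integer"), ("SUBJECT_ID", "integer"), ("HADM_ID", "integer"),
              ("ADMITTIME", "datetime"), ("DISCHTIME", "datetime"),
              ("ADMISSION_TYPE", "string"), ("ADMISSION_LOCATION", "string"),
              ("INSURANCE", "string"), ("DIAGNOSIS", "string", True),
              ("HOSPITAL_EXPIRE_FLAG", "integer")),
        ("HADM_ID",),
        (_FK_PAT,),
    ),
    TableSchema(
        "ICUSTAYS",
        _cols(("ROW_ID", "integer"), ("SUBJECT_ID", "integer"), ("HADM_ID", "integer"),
              ("ICUSTAY_ID", "integer"), ("FIRST_CAREUNIT", "string"),
              ("LAST_CAREUNIT", "string"), ("INTIME", "datetime"),
              ("OUTTIME", "datetime"), ("LOS", "decimal")),
        ("ICUSTAY_ID",),
        (_FK_PAT, _FK_ADM),
    ),
    TableSchema(
        "DIAGNOSES_ICD",
        _cols(("ROW_ID", "integer"), ("SUBJECT_ID", "integer"), ("HADM_ID", "integer"),
              ("SEQ_NUM", "integer"), ("ICD9_CODE", "code")),
        ("ROW_ID",),
        (_FK_PAT, _FK_ADM),
    ),
    TableSchema(
        "PROCEDURES_ICD",
        _cols(("ROW_ID", "integer"), ("SUBJECT_ID", "integer"), ("HADM_ID", "integer"),
              ("SEQ_NUM", "integer"), ("ICD9_CODE", "code")),
        ("ROW_ID",),
        (_FK_PAT, _FK_ADM),
    ),
    TableSchema(
        "PRESCRIPTIONS",
        _cols(("ROW_ID", "integer"), ("SUBJECT_ID", "integer"), ("HADM_ID", "integer"),
              ("ICUSTAY_ID", "integer", True), ("STARTDATE", "datetime"),
              ("ENDDATE", "datetime", True), ("DRUG_TYPE", "string"),
              ("DRUG", "string"), ("DOSE_VAL_RX", "string", True),
              ("DOSE_UNIT_RX", "string", True), ("ROUTE", "string", True)),
        ("ROW_ID",),
        (_FK_PAT, _FK_ADM, _FK_ICU),
    ),
    TableSchema(
        "LABEVENTS",
        _cols(("ROW_ID", "integer"), ("SUBJECT_ID", "integer"),
              ("HADM_ID", "integer", True), ("ITEMID", "integer"),
              ("CHARTTIME", "datetime"), ("VALUE", "string", True),
              ("VALUENUM", "decimal", True), ("VALUEUOM", "string", True),
              ("FLAG", "string", True)),
        ("ROW_ID",),
        (_FK_PAT, _FK_ADM, ForeignKey("ITEMID", "D_LABITEMS", "ITEMID")),
    ),
    TableSchema(
        "D_LABITEMS",
        _cols(("ROW_ID", "integer"), ("ITEMID", "integer"), ("LABEL", "string"),
              ("FLUID", "string"), ("CATEGORY", "string"),
              ("LOINC_CODE", "code", True)),
        ("ITEMID",),
    ),
    TableSchema(
        "D_ICD_DIAGNOSES",
        _cols(("ROW_ID", "integer"), ("ICD9_CODE", "code"),
              ("SHORT_TITLE", "string"), ("LONG_TITLE", "string")),
        ("ICD9_CODE",),
    ),
    TableSchema(
        "CAREGIVERS",
        _cols(("ROW_ID", "integer"), ("CGID", "code"), ("LABEL", "string"),
              ("DESCRIPTION", "string", True)),
        ("CGID",),
    ),
    TableSchema(
        "TRANSFERS",
        _cols(("ROW_ID", "integer"), ("SUBJECT_ID", "integer"), ("HADM_ID", "integer"),
              ("ICUSTAY_ID", "integer", True), ("EVENTTYPE", "string"),
              ("PREV_CAREUNIT", "string", True), ("CURR_CAREUNIT", "string", True),
              ("INTIME", "datetime"), ("OUTTIME", "datetime", True)),
        ("ROW_ID",),
        (_FK_PAT, _FK_ADM, _FK_ICU),
    ),
    TableSchema(
        "SERVICES",
        _cols(("ROW_ID", "integer"), ("SUBJECT_ID", "integer"), ("HADM_ID", "integer"),
              ("TRANSFERTIME", "datetime"), ("PREV_SERVICE", "string", True),
              ("CURR_SERVICE", "string")),
        ("ROW_ID",),
        (_FK_PAT, _FK_ADM),
    ),
    TableSchema(
        "CALLOUT",
        _cols(("ROW_ID", "integer"), ("SUBJECT_ID", "integer"), ("HADM_ID", "integer"),
              ("SUBMIT_WARDID", "integer"), ("CALLOUT_SERVICE", "string"),
              ("CALLOUT_STATUS", "string"), ("CREATETIME", "datetime"),
              ("OUTCOMETIME", "datetime", True)),
        ("ROW_ID",),
        (_FK_PAT, _FK_ADM),
    ),
)

# Remaining files in the standard v1.4 distribution (name + key only).
# "MICROBIOLOGY" in descriptive sources is canonicalized to MICROBIOLOGYEVENTS.
_STUB_TABLE_NAMES: tuple[str, ...] = (
    "CHARTEVENTS", "CPTEVENTS", "D_CPT", "D_ICD_PROCEDURES", "D_ITEMS",
    "DATETIMEEVENTS", "DRGCODES", "INPUTEVENTS_CV", "INPUTEVENTS_MV",
    "MICROBIOLOGYEVENTS", "NOTEEVENTS", "OUTPUTEVENTS", "PROCEDUREEVENTS_MV",
)

CORE_TABLE_NAMES: tuple[str, ...] = tuple(t.file_name for t in _CORE_TABLES)


def table_registry() -> list[TableSchema]:
    """Registry of all 26 MIMIC-III v1.4 CSV files.

    Core tables (those the mapping and generator exercise) carry full
    column lists; the remainder are listed with name and key only.
    """
    stubs = [
        TableSchema(name, _cols(("ROW_ID", "integer")), ("ROW_ID",))
        for name in _STUB_TABLE_NAMES
    ]
    return sorted(list(_CORE_TABLES) + stubs, key=lambda t: t.file_name)


def registry_table(name: str) -> TableSchema:
    for t in table_registry():
        if t.file_name == name.upper():
            return t
    raise KeyError(name)


# ---------------------------------------------------------------------------
# Datatype-property catalogue, derived from the core table registry
# ---------------------------------------------------------------------------

#: Which ontology class each core table's rows instantiate.
TABLE_CLASS: dict[str, str] = {
    "PATIENTS": "Patient",
    "ADMISSIONS": "Admission",
    "ICUSTAYS": "ICU_Stays",
    "DIAGNOSES_ICD": "ICD_Diagnosis",
    "PROCEDURES_ICD": "ICD_Procedure",
    "PRESCRIPTIONS": "Prescription",
    "LABEVENTS": "Lab_Event",
    "D_LABITEMS": "Lab_Item",
    "D_ICD_DIAGNOSES": "ICD_Diagnosis_Code",
    "CAREGIVERS": "CareGivers",
    "TRANSFERS": "Transfers",
    "SERVICES": "Services",
    "CALLOUT": "Callout",
}


def _build_datatype_properties() -> tuple[DatatypePropertyDef, ...]:
    by_name: dict[str, dict] = {}
    for table in _CORE_TABLES:
        cls = TABLE_CLASS[table.file_name]
        for col in table.columns:
            name = col.name.lower()
            entry = by_name.setdefault(
                name, {"domains": [], "literal_type": col.literal_type, "sources": []}
            )
            if col.literal_type != entry["literal_type"]:
                raise ValueError(
                    f"column {name} declared with conflicting literal types"
                )
            if cls not in entry["domains"]:
                entry["domains"].append(cls)
            entry["sources"].append(f"{table.file_name}.{col.name}")
    return tuple(
        DatatypePropertyDef(
            name=name,
            domains=tuple(sorted(e["domains"])),
            literal_type=e["literal_type"],
            sources=tuple(sorted(e["sources"])),
        )
        for name, e in sorted(by_name.items())
    )


def build_mimic_schema() -> OntologySchema:
    """The built-in EHR ontology: every class, the 19 object properties,
    and the datatype-property catalogue derived from the core tables."""
    props = tuple(
        replace(p, domains=tuple(sorted(p.domains)))
        for p in sorted(_OBJECT_PROPERTIES, key=lambda p: p.name)
    )
    return OntologySchema(
        classes=tuple(sorted(_CLASSES, key=lambda c: c.name)),
        object_properties=props,
        datatype_properties=_build_datatype_properties(),
        base_iri=BASE_IRI,
        prefix=PREFIX,
    )


# ---------------------------------------------------------------------------
# Structural validation
# ---------------------------------------------------------------------------

def validate_schema(schema: OntologySchema) -> list[ValidationIssue]:
    """Structural consistency check.

    Empty report iff: class names unique, every parent declared, the
    subclass relation is acyclic, every property domain/range resolves
    to a declared class, and property names are unique with disjoint
    object/datatype namespaces.
    """
    issues: list[ValidationIssue] = []
    names = [c.name for c in schema.classes]
    declared = set(names)
    for name in sorted({n for n in names if names.count(n) > 1}):
        issues.append(ValidationIssue("DUPLICATE_NAME", name, "class declared more than once"))

    cmap = {c.name: c for c in schema.classes}
    for c in schema.classes:
        if c.parent != ROOT and c.parent not in declared:
            issues.append(ValidationIssue("UNDECLARED_PARENT", c.name, f"parent {c.parent!r} is not a declared class"))

    # Cycle detection on the parent chain (white/grey/black DFS).
    color: dict[str, int] = {}
    reported: set[frozenset] = set()
    for start in cmap:
        if color.get(start):
            continue
        path: list[str] = []
        cur = start
        while cur != ROOT and cur in cmap and color.get(cur) != 2:
            if cur in path:
                cyc = frozenset(path[path.index(cur):])
                if cyc not in reported:
                    reported.add(cyc)
                    issues.append(ValidationIssue(
                        "CYCLE", "->".join(sorted(cyc)),
                        "subclass relation contains a cycle"))
                break
            path.append(cur)
            cur = cmap[cur].parent
        for n in path:
            color[n] = 2

    op_names = [p.name for p in schema.object_properties]
    dp_names = [p.name for p in schema.datatype_properties]
    for name in sorted({n for n in op_names if op_names.count(n) > 1} |
                       {n for n in dp_names if dp_names.count(n) > 1}):
        issues.append(ValidationIssue("DUPLICATE_NAME", name, "property declared more than once"))
    for name in sorted(set(op_names) & set(dp_names)):
        issues.append(ValidationIssue("NAMESPACE_CLASH", name, "name used as both object and datatype property"))

    for p in schema.object_properties:
        for d in p.domains:
            if d not in declared:
                issues.append(ValidationIssue("UNDECLARED_CLASS", p.name, f"domain {d!r} is not a declared class"))
        if p.range not in declared:
            issues.append(ValidationIssue("UNDECLARED_CLASS", p.name, f"range {p.range!r} is not a declared class"))
    for p in schema.datatype_properties:
        for d in p.domains:
            if d not in declared:
                issues.append(ValidationIssue("UNDECLARED_CLASS", p.name, f"domain {d!r} is not a declared class"))
        if p.literal_type not in LITERAL_TYPES:
            issues.append(ValidationIssue("BAD_LITERAL_TYPE", p.name, f"unknown literal type {p.literal_type!r}"))
    return issues


# ---------------------------------------------------------------------------
# OWL serialization / parsing
# ---------------------------------------------------------------------------

# Annotation predicates used to round-trip bookkeeping fields.
_P_SOURCE_TABLE = MC["sourceTable"]
_P_SOURCE = MC["source"]
_P_LITERAL_TYPE = MC["literalType"]

_FORMATS = {"turtle": "turtle", "rdfxml": "xml"}


class OntologyFormatError(ValueError):
    pass


class OntologyParseError(ValueError):
    pass


def _domain_node(g: Graph, schema: OntologySchema, domains: tuple[str, ...]):
    if len(domains) == 1:
        return schema.iri(domains[0])
    node = BNode()
    g.add((node, RDF.type, OWL.Class))
    lst = BNode()
    Collection(g, lst, [schema.iri(d) for d in domains])
    g.add((node, OWL.unionOf, lst))
    return node


def ontology_to_rdflib(schema: OntologySchema) -> Graph:
    g = Graph()
    g.bind(schema.prefix, Namespace(schema.base_iri))
    g.bind("owl", OWL)
    for c in sorted(schema.classes, key=lambda c: c.name):
        s = schema.iri(c.name)
        g.add((s, RDF.type, OWL.Class))
        parent = OWL.Thing if c.parent == ROOT else schema.iri(c.parent)
        g.add((s, RDFS.subClassOf, parent))
        if c.description:
            g.add((s, RDFS.comment, Literal(c.description)))
        for t in c.source_tables:
            g.add((s, _P_SOURCE_TABLE, Literal(t)))
    for p in sorted(schema.object_properties, key=lambda p: p.name):
        s = schema.iri(p.name)
        g.add((s, RDF.type, OWL.ObjectProperty))
        g.add((s, RDFS.domain, _domain_node(g, schema, p.domains)))
        g.add((s, RDFS.range, schema.iri(p.range)))
        g.add((s, _P_SOURCE_TABLE, Literal(p.source_table)))
    for p in sorted(schema.datatype_properties, key=lambda p: p.name):
        s = schema.iri(p.name)
        g.add((s, RDF.type, OWL.DatatypeProperty))
        g.add((s, RDFS.domain, _domain_node(g, schema, p.domains)))
        g.add((s, RDFS.range, _XSD_FOR_TYPE[p.literal_type]))
        g.add((s, _P_LITERAL_TYPE, Literal(p.literal_type)))
        for src in p.sources:
            g.add((s, _P_SOURCE, Literal(src)))
    return g


def serialize_ontology(schema: OntologySchema, format: str = "turtle") -> str:
    """Serialize to Turtle or RDF/XML, with union domains as owl:unionOf."""
    if format not in _FORMATS:
        raise OntologyFormatError(f"unsupported ontology format: {format!r}")
    return ontology_to_rdflib(schema).serialize(format=_FORMATS[format])


def _read_domains(g: Graph, node, base: str) -> tuple[str, ...]:
    if isinstance(node, URIRef):
        return (str(node)[len(base):],)
    lst = g.value(node, OWL.unionOf)
    if lst is None:
        raise OntologyParseError("domain blank node without owl:unionOf")
    members = [str(m)[len(base):] for m in Collection(g, lst)]
    return tuple(sorted(members))


def parse_ontology(document: str, format: str = "turtle") -> OntologySchema:
    """Inverse of :func:`serialize_ontology` on its image."""
    if format not in _FORMATS:
        raise OntologyFormatError(f"unsupported ontology format: {format!r}")
    g = Graph()
    try:
        g.parse(data=document, format=_FORMATS[format])
    except Exception as exc:  # rdflib raises several syntax-error types
        raise OntologyParseError(str(exc)) from exc

    base = BASE_IRI
    prefix = PREFIX
    for pfx, ns in g.namespaces():
        if str(ns) == base:
            prefix = pfx

    def local(iri) -> str:
        return str(iri)[len(base):]

    classes = []
    for s in sorted(set(g.subjects(RDF.type, OWL.Class))):
        if not isinstance(s, URIRef):
            continue  # union-domain helper classes
        parent_node = g.value(s, RDFS.subClassOf)
        parent = ROOT if parent_node == OWL.Thing or parent_node is None else local(parent_node)
        desc = g.value(s, RDFS.comment)
        classes.append(ClassDef(
            name=local(s),
            parent=parent,
            description=str(desc) if desc else "",
            source_tables=tuple(sorted(str(t) for t in g.objects(s, _P_SOURCE_TABLE))),
        ))

    obj_props = []
    for s in sorted(set(g.subjects(RDF.type, OWL.ObjectProperty))):
        obj_props.append(ObjectPropertyDef(
            name=local(s),
            domains=_read_domains(g, g.value(s, RDFS.domain), base),
            range=local(g.value(s, RDFS.range)),
            source_table=str(g.value(s, _P_SOURCE_TABLE) or ""),
        ))

    dt_props = []
    for s in sorted(set(g.subjects(RDF.type, OWL.DatatypeProperty))):
        lit = g.value(s, _P_LITERAL_TYPE)
        dt_props.append(DatatypePropertyDef(
            name=local(s),
            domains=_read_domains(g, g.value(s, RDFS.domain), base),
            literal_type=str(lit) if lit else "string",
            sources=tuple(sorted(str(t) for t in g.objects(s, _P_SOURCE))),
        ))

    schema = OntologySchema(
        classes=tuple(sorted(classes, key=lambda c: c.name)),
        object_properties=tuple(sorted(obj_props, key=lambda p: p.name)),
        datatype_properties=tuple(sorted(dt_props, key=lambda p: p.name)),
        base_iri=base,
        prefix=prefix,
    )
    return schema
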