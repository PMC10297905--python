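"""CSV-to-RDF mapping for MIMIC-III-shaped tables.

Each CSV row becomes a small star of subject-predicate-object triples:
one ``rdf:type`` assertion for the row's entity, one literal triple per
mapped column, and one object-property link per resolvable foreign key.
Subjects are minted deterministically under the base IRI
``http://mimicIII.com/base/`` as ``{base}{Class}/{key1[-key2...]}`` with
percent-encoded key segments, so every IRI parses back to its (class,
keys) origin.

Demographic fields (gender, race, marital status) are emitted as
*resources* (``mc:gender mc:Male``) through a fixed vocabulary map;
codes and identifiers stay string literals (``mc:icd9_code "41401"``);
everything else is typed by column (integer, decimal, dateTime).

Null handling: empty strings, whitespace and the sentinel ``NULL``
(case-insensitive) are treated as absent and produce no triple.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Union
from urllib.parse import quote, unquote

from rdflib import Graph as RdflibGraph
from rdflib import Literal as RdflibLiteral
from rdflib import URIRef
from rdflib.namespace import RDF, XSD

from .ontology import (
    BASE_IRI,
    PREFIX,
    OntologySchema,
    TableSchema,
    registry_table,
)

RDF_TYPE = str(RDF.type)

#: Sentinel returned by :func:`make_literal` for null cell values.
ABSENT = object()

_NULL_SENTINELS = {"", "null"}

_XSD_FOR = {
    "string": None,
    "code": None,
    "categorical": None,
    "integer": str(XSD.integer),
    "decimal": str(XSD.decimal),
    "datetime": str(XSD.dateTime),
}
_TYPE_FOR_XSD = {
    str(XSD.integer): "integer",
    str(XSD.decimal): "decimal",
    str(XSD.dateTime): "datetime",
}

_INT_RE = re.compile(r"^[+-]?\d+$")
_DEC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_DT_RE = re.compile(r"^\d{4}-\d{2}-\d{2}[ T]\d{2}:\d{2}:\d{2}$")
_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


class MintingError(ValueError):
    pass


class LiteralCoercionError(ValueError):
    pass


class RowError(ValueError):
    pass


class CsvSchemaError(ValueError):
    pass


class DatasetError(ValueError):
    pass


class GraphParseError(ValueError):
    pass


class GraphFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Iri:
    value: str

    def n3(self) -> str:
        return f"<{self.value}>"


class TypedLiteral:
    """A literal with a lexical form and a declared type.

    Equality and hashing use the *RDF-level* type (the XSD datatype the
    literal maps to), so a ``code`` literal written out and read back as
    a plain string compares equal.
    """

    __slots__ = ("lexical", "literal_type")

    def __init__(self, lexical: str, literal_type: str = "string"):
        if lexical == "":
            raise ValueError("literal lexical form must be nonempty")
        self.lexical = lexical
        self.literal_type = literal_type

    @property
    def xsd_type(self) -> Optional[str]:
        return _XSD_FOR[self.literal_type]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TypedLiteral)
            and self.lexical == other.lexical
            and self.xsd_type == other.xsd_type
        )

    def __hash__(self) -> int:
        return hash((self.lexical, self.xsd_type))

    def __repr__(self) -> str:
        return f"TypedLiteral({self.lexical!r}, {self.literal_type!r})"

    def to_rdflib(self) -> RdflibLiteral:
        if self.xsd_type is None:
            return RdflibLiteral(self.lexical)
        return RdflibLiteral(self.lexical, datatype=URIRef(self.xsd_type))

    def n3(self) -> str:
        return self.to_rdflib().n3()


Node = Union[Iri, TypedLiteral]


@dataclass(frozen=True)
class Triple:
    subject: Iri
    predicate: Iri
    object: Node

    def n3(self) -> str:
        return f"{self.subject.n3()} {self.predicate.n3()} {self.object.n3()} ."


class TripleGraph:
    """A duplicate-free collection of triples with prefix bindings."""

    def __init__(self, triples: Iterable[Triple] = (), bindings: Optional[dict] = None):
        self._triples: set[Triple] = set(triples)
        self.bindings: dict[str, str] = {PREFIX: BASE_IRI, "rdf": str(RDF), "xsd": str(XSD)}
        if bindings:
            self.bindings.update(bindings)

    def add(self, triple: Triple) -> None:
        self._triples.add(triple)

    def update(self, other: "TripleGraph") -> None:
        self._triples |= other._triples
        self.bindings.update(other.bindings)

    @property
    def triples(self) -> frozenset:
        return frozenset(self._triples)

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self):
        return iter(self._triples)

    def __contains__(self, t: Triple) -> bool:
        return t in self._triples

    def __eq__(self, other) -> bool:
        return isinstance(other, TripleGraph) and self._triples == other._triples

    def to_rdflib(self) -> RdflibGraph:
        g = RdflibGraph()
        for prefix, iri in self.bindings.items():
            g.bind(prefix, iri, override=True)
        for t in self._triples:
            obj = URIRef(t.object.value) if isinstance(t.object, Iri) else t.object.to_rdflib()
            g.add((URIRef(t.subject.value), URIRef(t.predicate.value), obj))
        return g

    @classmethod
    def from_rdflib(cls, g: RdflibGraph) -> "TripleGraph":
        out = cls()
        for s, p, o in g:
            if not isinstance(s, URIRef) or not isinstance(p, URIRef):
                raise GraphParseError("blank-node subjects/predicates are not supported")
            if isinstance(o, RdflibLiteral):
                dt = str(o.datatype) if o.datatype else None
                obj: Node = TypedLiteral(str(o), _TYPE_FOR_XSD.get(dt, "string"))
            elif isinstance(o, URIRef):
                obj = Iri(str(o))
            else:
                raise GraphParseError("blank-node objects are not supported")
            out.add(Triple(Iri(str(s)), Iri(str(p)), obj))
        return out


# ---------------------------------------------------------------------------
# IRI minting
# ---------------------------------------------------------------------------

def _encode_segment(value: str) -> str:
    # "-" joins composite keys, so it is escaped inside each segment to
    # keep the template invertible.
    return quote(value, safe="").replace("-", "%2D")


def mint_iri(entity_class: str, key_values: Iterable[str], base_iri: str = BASE_IRI) -> Iri:
    """Deterministic subject IRI: ``{base}{Class}/{key1[-key2...]}``."""
    keys = [str(k).strip() for k in key_values]
    if not keys or any(k == "" for k in keys):
        raise MintingError(f"empty key value while minting {entity_class} IRI")
    path = "-".join(_encode_segment(k) for k in keys)
    return Iri(f"{base_iri}{entity_class}/{path}")


def parse_iri(iri: Iri, base_iri: str = BASE_IRI) -> tuple[str, list[str]]:
    """Inverse of :func:`mint_iri`: recover (class, key values)."""
    value = iri.value
    if not value.startswith(base_iri):
        raise MintingError(f"IRI {value!r} not under base {base_iri!r}")
    rest = value[len(base_iri):]
    cls, _, path = rest.partition("/")
    if not cls or not path:
        raise MintingError(f"IRI {value!r} does not follow the minting template")
    return cls, [unquote(seg) for seg in path.split("-")]


# ---------------------------------------------------------------------------
# Literals and categorical resources
# ---------------------------------------------------------------------------

def is_null(raw: Optional[str]) -> bool:
    return raw is None or raw.strip().lower() in _NULL_SENTINELS


def make_literal(raw: Optional[str], literal_type: str):
    """Typed literal from a raw CSV cell, or :data:`ABSENT` for nulls.

    Datetimes ``YYYY-MM-DD HH:MM:SS`` are normalized to ISO 8601 with a
    ``T`` separator; bare dates get ``T00:00:00``.  Numeric lexicals are
    validated, not reformatted.
    """
    if is_null(raw):
        return ABSENT
    value = raw.strip()
    if literal_type == "integer":
        if not _INT_RE.match(value):
            raise LiteralCoercionError(f"not an integer lexical: {value!r}")
    elif literal_type == "decimal":
        if not _DEC_RE.match(value):
            raise LiteralCoercionError(f"not a decimal lexical: {value!r}")
    elif literal_type == "datetime":
        if _DATE_RE.match(value):
            value = value + " 00:00:00"
        if not _DT_RE.match(value):
            raise LiteralCoercionError(f"not a datetime lexical: {value!r}")
        value = value.replace(" ", "T")
    return TypedLiteral(value, literal_type)


#: Raw-value -> resource local-name map for the demographic fields.
CATEGORICAL_VOCAB: dict[str, dict[str, str]] = {
    "gender": {"M": "Male", "F": "Female"},
    "race": {
        "WHITE": "White",
        "BLACK": "Black",
        "ASIAN": "Asian",
        "HISPANIC": "Hispanic",
        "OTHER": "Other",
        "UNKNOWN": "Unknown",
    },
    "marital_status": {
        "MARRIED": "Married",
        "SINGLE": "Single",
        "DIVORCED": "Divorced",
        "WIDOWED": "Widowed",
        "SEPARATED": "Separated",
        "UNKNOWN": "Unknown",
    },
}


class UnmappedValue(ValueError):
    pass


def categorical_resource(property_name: str, raw: str, base_iri: str = BASE_IRI) -> Iri:
    """Resource IRI for a categorical value, e.g. (gender, "M") -> mc:Male."""
    vocab = CATEGORICAL_VOCAB.get(property_name)
    if vocab is None:
        raise UnmappedValue(f"{property_name!r} is not a categorical property")
    local = vocab.get(raw.strip().upper())
    if local is None:
        raise UnmappedValue(f"value {raw!r} outside the {property_name} vocabulary")
    return Iri(base_iri + local)


# ---------------------------------------------------------------------------
# Table mappings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnRule:
    column: str
    property_name: str
    literal_type: str  # "categorical" means resource emission


@dataclass(frozen=True)
class LinkRule:
    """Foreign-key link emission.

    ``subject_side`` is ``"target"`` when the FK target is the triple's
    subject (the usual case: ⟨Patient, HAS_ADMISSION, Admission⟩ emitted
    from an ADMISSIONS row) and ``"row"`` when the row entity is the
    subject (⟨Lab_Event, HAS_LAB_ITEM, Lab_Item⟩).
    """

    columns: tuple[str, ...]
    property_name: str
    target_class: str
    subject_side: str = "target"


RowFilter = Union[Callable[[Mapping[str, str]], bool], tuple]


@dataclass(frozen=True)
class TableMapping:
    table_name: str
    subject_class: str
    subject_key_columns: tuple[str, ...]
    column_rules: tuple[ColumnRule, ...]
    link_rules: tuple[LinkRule, ...] = ()
    row_filter: Optional[RowFilter] = None


_FILTER_OPS = {
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    "startswith": lambda a, b: a.startswith(b),
}


def _passes_filter(row: Mapping[str, str], flt: Optional[RowFilter]) -> bool:
    if flt is None:
        return True
    if callable(flt):
        return bool(flt(row))
    column, op, value = flt
    return _FILTER_OPS[op]((row.get(column.upper()) or "").strip(), value)


@dataclass
class Warning_:
    code: str
    table: str
    column: str
    message: str


@dataclass
class TableReport:
    table: str
    rows_read: int = 0
    rows_skipped: int = 0
    triples_emitted: int = 0
    warnings: list = field(default_factory=list)
    errors: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "table": self.table,
            "rows_read": self.rows_read,
            "rows_skipped": self.rows_skipped,
            "triples_emitted": self.triples_emitted,
            "warnings": [vars(w) for w in self.warnings],
            "errors": list(self.errors),
        }


@dataclass
class MappingReport:
    tables: list = field(default_factory=list)

    @property
    def total_triples(self) -> int:
        return sum(t.triples_emitted for t in self.tables)

    def to_dict(self) -> dict:
        return {"tables": [t.to_dict() for t in self.tables],
                "total_triples": self.total_triples}


def map_row(
    mapping: TableMapping,
    row: Mapping[str, str],
    schema: OntologySchema,
    warnings: Optional[list] = None,
) -> list[Triple]:
    """Triples for one CSV row: type assertion + literals + FK links.

    With a ``warnings`` list, coercion failures and out-of-vocabulary
    categorical values are recorded there (the latter fall back to a
    plain string literal); without one, they raise.
    """
    row = {k.upper(): v for k, v in row.items()}
    keys = [row.get(c) for c in mapping.subject_key_columns]
    if any(is_null(k) for k in keys):
        raise RowError(
            f"{mapping.table_name}: null key column in {mapping.subject_key_columns}"
        )
    if not _passes_filter(row, mapping.row_filter):
        return []
    subject = mint_iri(mapping.subject_class, keys, schema.base_iri)
    triples = [Triple(subject, Iri(RDF_TYPE), Iri(schema.base_iri + mapping.subject_class))]

    for rule in mapping.column_rules:
        raw = row.get(rule.column)
        if is_null(raw):
            continue
        pred = Iri(schema.base_iri + rule.property_name)
        if rule.literal_type == "categorical":
            try:
                obj: Node = categorical_resource(rule.property_name, raw, schema.base_iri)
            except UnmappedValue as exc:
                if warnings is None:
                    raise
                warnings.append(Warning_("UNMAPPED_VALUE", mapping.table_name,
                                         rule.column, str(exc)))
                obj = TypedLiteral(raw.strip(), "string")
        else:
            try:
                lit = make_literal(raw, rule.literal_type)
            except LiteralCoercionError as exc:
                if warnings is None:
                    raise LiteralCoercionError(
                        f"{mapping.table_name}.{rule.column}: {exc}") from exc
                warnings.append(Warning_("COERCION", mapping.table_name,
                                         rule.column, str(exc)))
                continue
            if lit is ABSENT:
                continue
            obj = lit
        triples.append(Triple(subject, pred, obj))

    for link in mapping.link_rules:
        values = [row.get(c) for c in link.columns]
        if any(is_null(v) for v in values):
            continue
        target = mint_iri(link.target_class, values, schema.base_iri)
        pred = Iri(schema.base_iri + link.property_name)
        if link.subject_side == "target":
            triples.append(Triple(target, pred, subject))
        else:
            triples.append(Triple(subject, pred, target))
    return triples


def _open_csv(csv_source) -> Iterable[dict]:
    if isinstance(csv_source, (str, Path)):
        handle = open(csv_source, newline="", encoding="utf-8")
        close = True
    else:
        handle, close = csv_source, False
    try:
        reader = csv.DictReader(handle)
        yield reader.fieldnames or []
        for row in reader:
            yield row
    finally:
        if close:
            handle.close()


def check_header(table: TableSchema, header: Iterable[str]) -> None:
    got = {h.strip().upper() for h in header}
    want = set(table.column_names())
    if got != want:
        missing = sorted(want - got)
        extra = sorted(got - want)
        raise CsvSchemaError(
            f"{table.file_name}: header mismatch; missing {missing}, extra {extra}"
        )


def map_table(
    mapping: TableMapping,
    csv_source,
    schema: OntologySchema,
) -> tuple[TripleGraph, TableReport]:
    """Map one CSV file/stream to a triple graph (streaming, set semantics)."""
    table = registry_table(mapping.table_name)
    report = TableReport(table=mapping.table_name)
    graph = TripleGraph()
    rows = _open_csv(csv_source)
    header = next(rows)
    check_header(table, header)
    for row in rows:
        report.rows_read += 1
        try:
            triples = map_row(mapping, row, schema, warnings=report.warnings)
        except (RowError, MintingError) as exc:
            report.rows_skipped += 1
            report.errors.append(str(exc))
            continue
        for t in triples:
            graph.add(t)
    report.triples_emitted = len(graph)
    return graph, report


def map_dataset(
    directory,
    schema: OntologySchema,
    mappings: Mapping[str, TableMapping],
    required: Optional[Iterable[str]] = None,
) -> tuple[TripleGraph, MappingReport]:
    """Map every mapped CSV file in ``directory`` and union the graphs."""
    directory = Path(directory)
    required = set(required if required is not None else mappings.keys())
    missing = sorted(
        t for t in required if not (directory / f"{t}.csv").exists()
    )
    if missing:
        raise DatasetError(f"missing required tables: {missing}")
    graph = TripleGraph()
    report = MappingReport()
    for name in sorted(mappings):
        path = directory / f"{name}.csv"
        if not path.exists():
            continue
        tgraph, treport = map_table(mappings[name], path, schema)
        graph.update(tgraph)
        report.tables.append(treport)
    return graph, report


# ---------------------------------------------------------------------------
# Conformance validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    code: str
    triple: str
    message: str


@dataclass
class ConformanceReport:
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations

    def codes(self) -> list[str]:
        return [v.code for v in self.violations]

    def to_dict(self) -> dict:
        return {"ok": self.ok, "violations": [vars(v) for v in self.violations]}


def _lexical_ok(lit: TypedLiteral, literal_type: str) -> bool:
    if literal_type == "integer":
        return bool(_INT_RE.match(lit.lexical))
    if literal_type == "decimal":
        return bool(_DEC_RE.match(lit.lexical))
    if literal_type == "datetime":
        return bool(re.match(r"^\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}$", lit.lexical))
    return True


def validate_graph(graph: TripleGraph, schema: OntologySchema) -> ConformanceReport:
    """Check every triple against the ontology's declarations.

    Domain checks are union-aware and subclass-aware: a subject conforms
    if any of its asserted classes sits at or below a member of the
    property's domain set.  Dangling links (a subject with no type
    assertion) surface as DOMAIN_VIOLATIONs.
    """
    base = schema.base_iri
    types: dict[str, set[str]] = {}
    for t in graph:
        if t.predicate.value == RDF_TYPE and isinstance(t.object, Iri):
            types.setdefault(t.subject.value, set()).add(t.object.value[len(base):])

    obj_props = {p.name: p for p in schema.object_properties}
    dt_props = {p.name: p for p in schema.datatype_properties}
    closure_cache: dict[tuple, set] = {}

    def domain_closure(domains: tuple[str, ...]) -> set[str]:
        if domains not in closure_cache:
            out: set[str] = set()
            for d in domains:
                out |= schema.descendants(d)
            closure_cache[domains] = out
        return closure_cache[domains]

    violations: list[Violation] = []
    for t in sorted(graph, key=lambda t: t.n3()):
        if t.predicate.value == RDF_TYPE:
            if isinstance(t.object, Iri) and not schema.has_class(t.object.value[len(base):]):
                violations.append(Violation(
                    "UNDECLARED_CLASS", t.n3(),
                    f"type assertion to undeclared class {t.object.value}"))
            continue
        if not t.predicate.value.startswith(base):
            violations.append(Violation("UNDECLARED_PREDICATE", t.n3(),
                                        f"predicate {t.predicate.value} outside schema"))
            continue
        pname = t.predicate.value[len(base):]
        if pname in obj_props:
            prop = obj_props[pname]
            subject_classes = types.get(t.subject.value, set())
            if not subject_classes & domain_closure(prop.domains):
                violations.append(Violation(
                    "DOMAIN_VIOLATION", t.n3(),
                    f"subject classes {sorted(subject_classes)} not in domain "
                    f"{sorted(prop.domains)} of {pname}"))
            if not isinstance(t.object, Iri):
                violations.append(Violation(
                    "RANGE_VIOLATION", t.n3(),
                    f"object of object property {pname} is a literal"))
            else:
                object_classes = types.get(t.object.value, set())
                if object_classes and not object_classes & domain_closure((prop.range,)):
                    violations.append(Violation(
                        "RANGE_VIOLATION", t.n3(),
                        f"object classes {sorted(object_classes)} not in range "
                        f"{prop.range} of {pname}"))
        elif pname in dt_props:
            prop = dt_props[pname]
            subject_classes = types.get(t.subject.value, set())
            if not subject_classes & domain_closure(prop.domains):
                violations.append(Violation(
                    "DOMAIN_VIOLATION", t.n3(),
                    f"subject classes {sorted(subject_classes)} not in domain "
                    f"{sorted(prop.domains)} of {pname}"))
            if isinstance(t.object, TypedLiteral):
                if prop.literal_type not in ("categorical",) and \
                        not _lexical_ok(t.object, prop.literal_type):
                    violations.append(Violation(
                        "LITERAL_TYPE_MISMATCH", t.n3(),
                        f"lexical {t.object.lexical!r} invalid for {prop.literal_type}"))
            else:
                # Categorical resources (mc:Male) are IRIs by design.
                if prop.literal_type != "categorical" or \
                        not t.object.value.startswith(base):
                    violations.append(Violation(
                        "LITERAL_TYPE_MISMATCH", t.n3(),
                        f"IRI object on datatype property {pname}"))
        else:
            violations.append(Violation(
                "UNDECLARED_PREDICATE", t.n3(),
                f"predicate {pname} not declared in the ontology"))
    return ConformanceReport(violations=violations)


# ---------------------------------------------------------------------------
# Graph serialization
# ---------------------------------------------------------------------------

def serialize_graph(graph: TripleGraph, format: str = "ntriples") -> str:
    """N-Triples (canonical: one sorted line per triple) or Turtle."""
    if format in ("ntriples", "nt"):
        lines = sorted(t.n3() for t in graph)
        return "\n".join(lines) + ("\n" if lines else "")
    if format in ("turtle", "ttl"):
        return graph.to_rdflib().serialize(format="turtle")
    raise GraphFormatError(f"unsupported graph format: {format!r}")


def parse_graph(text: str, format: str = "ntriples") -> TripleGraph:
    if format in ("ntriples", "nt"):
        fmt = "nt"
    elif format in ("turtle", "ttl"):
        fmt = "turtle"
    else:
        raise GraphFormatError(f"unsupported graph format: {format!r}")
    g = RdflibGraph()
    try:
        g.parse(data=text, format=fmt)
    except Exception as exc:
        raise GraphParseError(str(exc)) from exc
    return TripleGraph.from_rdflib(g)
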