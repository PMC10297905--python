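"""In-process triple store and the cohort analyses.

:func:`load` turns a :class:`~ehrkg.rdf_mapping.TripleGraph` into an
immutable queryable handle (backed by an rdflib graph with the ``mc``
prefix pre-bound).  :func:`query` evaluates SPARQL 1.1 SELECT queries.

The three cohort operations mirror the classic ICU research questions:

* patients carrying a diagnosis in an ICD-9 code family
  (default prefix ``250`` — diabetes mellitus),
* patients carrying diagnoses in two families (defaults ``401``
  essential hypertension and ``250`` — the comorbidity cohort),
* patients admitted to the ICU multiple times (default: at least two
  distinct ICU stays).

Diagnosis cohorts accept any code path the ontology declares: a direct
patient-to-care link, via an admission, or via an ICU stay.  Exact-code
matching (rather than prefix) is available with ``exact=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from rdflib import Graph as RdflibGraph
from rdflib import Literal as RdflibLiteral
from rdflib import URIRef
from rdflib.plugins.sparql import prepareQuery

from .ontology import BASE_IRI, PREFIX
from .rdf_mapping import Iri, TripleGraph, TypedLiteral, parse_iri

_TYPE_FOR_XSD = {
    "http://www.w3.org/2001/XMLSchema#integer": "integer",
    "http://www.w3.org/2001/XMLSchema#decimal": "decimal",
    "http://www.w3.org/2001/XMLSchema#dateTime": "datetime",
}

UNBOUND = None


class QueryError(ValueError):
    pass


class GraphHandle:
    """Opaque, immutable handle over a loaded triple collection."""

    def __init__(self, rdflib_graph: RdflibGraph):
        self._g = rdflib_graph

    def __len__(self) -> int:
        return len(self._g)

    @property
    def rdflib_graph(self) -> RdflibGraph:
        return self._g


@dataclass
class ResultTable:
    """A SPARQL solution sequence: variable names plus binding rows."""

    variables: list[str]
    rows: list[dict]

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, var: str) -> list:
        return [row[var] for row in self.rows]

    def canonical(self) -> list[tuple]:
        """Rows as sorted tuples of n3 forms, for order-free comparison."""
        def key(v):
            return "" if v is None else v.n3()
        return sorted(tuple(key(row[v]) for v in self.variables) for row in self.rows)


@dataclass
class CohortResult:
    """Patients satisfying a cohort criterion."""

    patients: set[Iri]
    counts: dict[Iri, int] = field(default_factory=dict)

    @property
    def subject_ids(self) -> set[int]:
        """SUBJECT_IDs recovered from the patient IRIs."""
        out = set()
        for iri in self.patients:
            _, keys = parse_iri(iri)
            out.add(int(keys[0]))
        return out

    def count_by_subject_id(self) -> dict[int, int]:
        return {int(parse_iri(iri)[1][0]): n for iri, n in self.counts.items()}


def load(graph: TripleGraph) -> GraphHandle:
    """Load a triple graph into a queryable handle (count-preserving)."""
    return GraphHandle(graph.to_rdflib())


def _to_node(term) -> Union[Iri, TypedLiteral, None]:
    if term is None:
        return UNBOUND
    if isinstance(term, URIRef):
        return Iri(str(term))
    if isinstance(term, RdflibLiteral):
        dt = str(term.datatype) if term.datatype else None
        return TypedLiteral(str(term), _TYPE_FOR_XSD.get(dt, "string"))
    raise QueryError(f"unsupported term in result: {term!r}")


def query(handle: GraphHandle, sparql_text: str) -> ResultTable:
    """Evaluate a SPARQL SELECT query; ``mc:`` is pre-bound."""
    ns = {PREFIX: BASE_IRI}
    try:
        prepared = prepareQuery(sparql_text, initNs=ns)
    except Exception as exc:
        raise QueryError(f"SPARQL syntax error: {exc}") from exc
    result = handle.rdflib_graph.query(prepared)
    if result.type != "SELECT":
        raise QueryError(f"unsupported query form: {result.type}")
    variables = [str(v) for v in result.vars]
    rows = [
        {v: _to_node(binding.get(v)) for v in variables}
        for binding in (dict(zip([str(x) for x in result.vars], r)) for r in result)
    ]
    return ResultTable(variables=variables, rows=rows)


# Each UNION branch is a self-contained pattern chain that starts from
# the (selective) diagnosis type/code and walks outward to the patient;
# the code filter sits inside the branch.  Two shapes are avoided on
# purpose because they are quadratic under the evaluator's bound-term
# reordering heuristic: a triple pattern after the UNION (it re-runs
# the union per candidate binding) and more than one rdf:type pattern
# per branch (two type patterns get evaluated first as a cross
# product).  The omitted type guards are implied by the link
# semantics anyway: only admissions are objects of HAS_ADMISSION and
# only ICU stays are objects of HAS_ICU_STAY.
_DX_PATHS = """
    {{ ?{dx} a mc:ICD_Diagnosis ; mc:icd9_code ?{code} .
       ?patient mc:HAS_PATIENT_CARE ?{dx} .
       {flt} }}
    UNION
    {{ ?{dx} a mc:ICD_Diagnosis ; mc:icd9_code ?{code} .
       ?{adm} mc:HAS_DIAGNOSIS ?{dx} .
       ?patient mc:HAS_ADMISSION ?{adm} .
       {flt} }}
    UNION
    {{ ?{dx} a mc:ICD_Diagnosis ; mc:icd9_code ?{code} .
       ?{icu} mc:HAS_DIAGNOSIS ?{dx} .
       ?{adm}2 mc:HAS_ICU_STAY ?{icu} .
       ?patient mc:HAS_ADMISSION ?{adm}2 .
       {flt} }}
"""


def _dx_block(tag: str, prefix: str, exact: bool) -> str:
    if exact:
        flt = f'FILTER(STR(?code{tag}) = "{prefix}")'
    else:
        flt = f'FILTER(STRSTARTS(STR(?code{tag}), "{prefix}"))'
    return _DX_PATHS.format(dx=f"dx{tag}", adm=f"adm{tag}", icu=f"icu{tag}",
                            code=f"code{tag}", flt=flt)


def cohort_by_diagnosis(handle: GraphHandle, code_prefix: str = "250",
                        exact: bool = False) -> CohortResult:
    """Patients with at least one ICD-9 diagnosis in the given code family."""
    if not code_prefix:
        raise ValueError("code_prefix must be nonempty")
    q = ("SELECT DISTINCT ?patient WHERE {\n"
         + _dx_block("", code_prefix, exact) + "}")
    table = query(handle, q)
    return CohortResult(patients=set(table.column("patient")))


def cohort_comorbid(handle: GraphHandle, prefix_a: str = "401",
                    prefix_b: str = "250", exact: bool = False) -> CohortResult:
    """Patients diagnosed in both code families (e.g. hypertension + diabetes).

    Defined as the intersection of the two single-family cohorts; each
    side is evaluated as its own SPARQL query (joining the two unions in
    a single query is quadratic in the engine used here).
    """
    if not prefix_a or not prefix_b:
        raise ValueError("both code prefixes must be nonempty")
    a = cohort_by_diagnosis(handle, prefix_a, exact=exact)
    b = cohort_by_diagnosis(handle, prefix_b, exact=exact)
    return CohortResult(patients=a.patients & b.patients)


def cohort_multi_icu(handle: GraphHandle, min_stays: int = 2) -> CohortResult:
    """Patients with at least ``min_stays`` distinct ICU stays, with counts."""
    if min_stays < 1:
        raise ValueError("min_stays must be >= 1")
    q = f"""
    SELECT ?patient (COUNT(DISTINCT ?icu) AS ?n) WHERE {{
      ?patient a mc:Patient ; mc:HAS_ADMISSION ?adm .
      ?adm mc:HAS_ICU_STAY ?icu .
    }}
    GROUP BY ?patient
    HAVING (COUNT(DISTINCT ?icu) >= {int(min_stays)})
    """
    table = query(handle, q)
    counts = {row["patient"]: int(row["n"].lexical) for row in table.rows}
    return CohortResult(patients=set(counts), counts=counts)
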