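# Methods

## Scope and design

`ehrkg` models the relational-to-semantic workflow for critical-care
EHR data: an OWL ontology over the MIMIC-III v1.4 table shapes, a
direct row-to-triples mapping, an in-process SPARQL store with cohort
analyses, and a synthetic-data generator whose planted ground truth
makes every step verifiable without credentialed data. The real
MIMIC-III distribution is never required; the package operates on any
directory of CSV files matching its table registry.

## Ontology

The class hierarchy has four structured branches — `Patient_Care`
(ICD-coded diagnoses and procedures), `Codes` (dictionary entries:
CPT, DRG, ICD diagnosis/procedure codes, lab items, charted items),
`Events` (chart, CPT, input, lab, microbiology, note, output) — plus
top-level classes for patients, admissions, ICU stays, prescriptions,
transfers, services, callouts and caregivers. Canonical identifiers
disambiguate names that recur across branches: `Events` subclasses take
an `_Event` suffix and `Codes` subclasses a `_Code` suffix, so the
ICD-diagnosis *record* (`ICD_Diagnosis`) is distinct from the
ICD-diagnosis *dictionary entry* (`ICD_Diagnosis_Code`). A declared
alias map (`ontology.CLASS_ALIASES`, test-covered) reconciles the
looser labels that appear in descriptive sources ("Diagnosis",
"Lab_Items", "Individual Item", "ICU Diagnosis Code", "patient.csv")
onto these canonical classes. The `Codes` branch includes a `DRG_Code`
class for DRGCODES.csv: diagnosis-related groups are not drugs, and the
occasional "Drug" label for this file is treated as a naming slip.

Nineteen object properties connect the classes. Where a relationship
is meaningful from several subject classes (`HAS_MEDICATION`,
`HAS_DIAGNOSIS`, `HAS_LAB_EVENTS`, …) the property declares a union
domain, serialized as an `owl:unionOf` class expression. Datatype
properties are named by lowercased column name; because the same column
name recurs across tables (`subject_id`, `hadm_id`, `icd9_code`,
`row_id`) while property IRIs must be unique, datatype properties also
carry union domains — one property per column name, with the set of
classes it appears on. Their literal types are `string`, `integer`,
`decimal`, `datetime`, `code` (kept verbatim as a string literal, the
right behaviour for ICD-9/LOINC/caregiver identifiers with leading
zeros), and `categorical`.

One deliberate divergence from the real MIMIC-III layout: gender, race
and marital status are patient-level datatype properties and are
generated into PATIENTS.csv, although MIMIC-III proper stores ethnicity
and marital status per admission. The demographic cohort queries this
package reproduces filter on the patient, so the patient-level
placement is the one that matches the query surface; it is confined to
the registry's PATIENTS column list and documented here.

The table registry enumerates all 26 files of the v1.4 distribution.
Thirteen "core" tables — the ones the generator populates and the
mapper consumes — carry full column lists, primary keys and foreign
keys; the remainder are registered by name and key only.
Validation of a schema is structural: unique names, declared parents,
an acyclic subclass relation, resolvable domains/ranges. Description-
logic reasoning is out of scope.

## CSV-to-RDF mapping

Each row of a mapped table yields one `rdf:type` assertion for the
row's entity, one literal triple per non-null mapped column, and one
object-property link per foreign key whose value is present. Subject
IRIs follow the template `{base}{Class}/{key1[-key2…]}` under the base
IRI `http://mimicIII.com/base/` (prefix `mc`); key segments are
percent-encoded with `-` additionally escaped, which makes the template
invertible — property tests round-trip arbitrary key text through
`mint_iri`/`parse_iri`.

Link rules record which side of the triple the row entity occupies: an
ADMISSIONS row emits ⟨Patient, `HAS_ADMISSION`, Admission⟩ (the foreign
key names the subject), while a LABEVENTS row emits ⟨Lab_Event,
`HAS_LAB_ITEM`, Lab_Item⟩ (the row entity is the subject). Union-domain
properties resolve per context column: a prescription row with both
HADM_ID and ICUSTAY_ID produces a medication link from the admission
*and* from the ICU stay, both sanctioned by the declared domain.

Null handling treats empty strings, whitespace and the sentinel `NULL`
(case-insensitive) as absent; absent values emit no triple. Datetimes
`YYYY-MM-DD HH:MM:SS` are normalized to ISO 8601 with a `T` separator.
Key columns are echoed as literals by default (`mc:subject_id "10001"`)
so SPARQL can filter on raw identifiers. Coercion failures and
out-of-vocabulary categorical values are collected as per-table report
warnings, not exceptions; a missing key column skips the row and is
counted. Graphs have set semantics: an exactly duplicated row
contributes nothing new, and the conservation law *triples = Σ rows (1 +
non-null columns + resolved links)* is tested against an independent
pandas scan of the same files.

Conformance validation checks every triple against the ontology:
undeclared predicates, domain membership (union-aware and
subclass-aware — a subject conforms if any asserted class sits at or
below a domain member), range membership, and lexical validity of
literals. A dangling foreign key surfaces as a DOMAIN_VIOLATION,
because the orphaned subject carries no type assertion.

Properties whose source rows live outside the generated core set
(`HAS_NOTE`, `HAS_CPT_CODE`, `HAS_DRG_CODE`, the dictionary-link
properties) or that would require cross-row joins
(`HAS_ICU_DIAGNOSIS_CODE`) are declared in the ontology but not emitted
by the default mappings; `HAS_ICD_DIAGNOSIS`/`HAS_ICD_PROCEDURE` are
likewise declared only, since the diagnosis row itself *is* the
`Patient_Care` instance and the patient links to it via
`HAS_PATIENT_CARE`. Mapping overrides (YAML, keyed by table) can add or
replace column rules, link rules and row filters.

Canonical N-Triples output is one sorted line per triple, so
serialize → parse → serialize is byte-stable; Turtle is supported for
interchange. Blank nodes and named graphs are out of scope.

## Triple store and cohort queries

Query evaluation delegates to rdflib's SPARQL 1.1 engine; the package
pins down the supported subset (SELECT, basic graph patterns, FILTER,
DISTINCT, GROUP BY, HAVING, COUNT) through its tests rather than the
engine. Two query shapes are deliberately avoided because rdflib's
BGP-reordering heuristic (sort by bound-term count) makes them
quadratic on graphs with ~10⁵ triples: triple patterns *after* a UNION
(the union is re-evaluated per candidate binding) and more than one
`rdf:type` pattern per group (all 2-bound-term patterns run first, as a
cross product). The diagnosis-cohort query therefore chains each UNION
branch from the selective diagnosis node outward to the patient and
relies on link ranges instead of redundant type guards; the comorbidity
cohort is computed as the set intersection of two single-family SPARQL
cohorts, which is also its definition. With these shapes, all three
cohorts on a 1000-patient graph (~163k triples) complete in about two
seconds; the naive forms took minutes.

Condition definitions are ICD-9 prefixes — `250` for diabetes mellitus,
`401` for essential hypertension — overridable per call and on the CLI;
exact-code matching is available via a flag. "Admitted to the ICU
multiple times" means ≥ 2 *distinct ICU stays* (not hospital
admissions), counted with `COUNT(DISTINCT …)` and reported per patient.

## Synthetic data generator

The generator emulates the MIMIC-III v1.4 file set at desk scale:
13 populated core tables with referential integrity (every HADM_ID
resolves to ADMISSIONS, every SUBJECT_ID to PATIENTS), temporal
ordering (ADMITTIME ≤ DISCHTIME, INTIME ≤ OUTTIME within the admission,
DOB before first admission), and header-only stubs for the remaining 13
registry files. Dates live in a far-future window (2100-01-01 to
2105-12-31 by default), echoing the date-shifting convention of
de-identified ICU data.

Cohorts are planted by exact count — `floor(fraction × n_patients)`
members each for diabetes (default 0.10), hypertension (0.08), their
overlap (0.03, drawn first so the comorbid set is exactly the
intersection) and multiple ICU stays (0.10) — rather than by Bernoulli
sampling, so realized sizes are deterministic for every seed. Two
guarantees make the planted sets *exact* rather than lower bounds: the
background diagnosis pool contains no code with prefix `250` or `401`,
and non-members of the multi-ICU cohort receive at most one ICU stay.
Consequently manifest, direct CSV scan and SPARQL must agree as sets,
and the test suite asserts exactly that, at n = 1000 and under
property-based variation of seed, size and fractions.

Each table draws from its own PCG64 stream seeded by `(seed,
crc32(table name))`, so adding a table never perturbs another's
content; identical specs produce byte-identical files. Admissions per
patient are `1 + Poisson(mean − 1)` (default mean 1.3); non-cohort
patients get one ICU stay with probability 0.7. Lab values, doses and
unit strings are plausible-typed filler — the generator makes no
clinical-realism claims, carries no value correlations, no free-text
notes, and no CHARTEVENTS-scale volume. Passing tests therefore
demonstrate pipeline correctness (mapping, conformance, query
semantics, determinism), not distributional fidelity to real ICU data.

The independent oracle (`oracle_scan`) recomputes each cohort by direct
CSV iteration with pandas — no RDF involved, sharing only the table
registry with the graph path. A perturbation helper injects exactly one
seeded defect (orphaned foreign key, inverted date pair, duplicated
row) for negative tests, and `check_integrity` reports
referential/temporal violations as data.

## Numerical and procedural choices

* Problem sizes: the acceptance pipeline runs at 1000 patients
  (~163k triples); unit and property tests use 0–100 patients. These
  sizes exercise every code path while keeping the full suite under a
  minute.
* Determinism: all randomness flows from explicit integer seeds through
  NumPy generators; serializations are canonically ordered
  (lexicographic for N-Triples; stable class/property ordering for the
  ontology documents).
* Tie-breaks and degenerate inputs: an empty population yields
  header-only files and empty cohorts; `min_stays = 1` degenerates to
  "any ICU stay"; a row filter or absent value simply suppresses
  triples; perturbation of an empty dataset is a fixture error.
* Literal equality uses the RDF-level datatype, so a `code` literal
  written out and read back as a plain string compares equal — this is
  what makes graph round-trip equality well-defined.

## Known limitations

* No DL reasoning, R2RML document support, SPARQL federation, blank
  nodes, named graphs, persistence or HTTP endpoint.
* The default mappings cover the 13 core tables; the other 13 registry
  files are recognized but pass through unmapped.
* rdflib's evaluator constrains usable query shapes at scale (see
  above); a store with a cost-based optimizer would lift that.
* Wall-clock query timing is environment-bound and intentionally not a
  correctness criterion anywhere in the suite.
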