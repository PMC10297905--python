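"""Default table-to-ontology mapping recipes.

One :class:`~ehrkg.rdf_mapping.TableMapping` per core MIMIC-III table,
derived from the table registry: every column becomes a datatype-property
rule named by its lowercased column name (the subject's key columns
included, so SPARQL can filter on raw identifiers), demographic columns
become categorical-resource rules, and foreign keys become object-property
links.

Union-domain properties (HAS_MEDICATION, HAS_TRANSFER, HAS_LAB_EVENTS)
get one link rule per context column: a prescription row with both
HADM_ID and ICUSTAY_ID set yields a link from the admission *and* one
from the ICU stay.

A YAML overrides file (keyed by table name) can replace column rules,
link rules, or attach a simple row filter::

    PRESCRIPTIONS:
      row_filter: {column: DRUG_TYPE, op: "==", value: MAIN}
      drop_columns: [DOSE_UNIT_RX]
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional

import yaml

from .ontology import TABLE_CLASS, registry_table
from .rdf_mapping import ColumnRule, LinkRule, TableMapping

# (table -> link rules); subject_side "target" emits ⟨fk-target, prop, row⟩.
_LINKS: dict[str, tuple[LinkRule, ...]] = {
    "ADMISSIONS": (LinkRule(("SUBJECT_ID",), "HAS_ADMISSION", "Patient"),),
    "ICUSTAYS": (LinkRule(("HADM_ID",), "HAS_ICU_STAY", "Admission"),),
    "DIAGNOSES_ICD": (
        LinkRule(("HADM_ID",), "HAS_DIAGNOSIS", "Admission"),
        LinkRule(("SUBJECT_ID",), "HAS_PATIENT_CARE", "Patient"),
    ),
    "PROCEDURES_ICD": (
        LinkRule(("HADM_ID",), "HAS_PROCEDURE", "Admission"),
        LinkRule(("SUBJECT_ID",), "HAS_PATIENT_CARE", "Patient"),
    ),
    "PRESCRIPTIONS": (
        LinkRule(("HADM_ID",), "HAS_MEDICATION", "Admission"),
        LinkRule(("ICUSTAY_ID",), "HAS_MEDICATION", "ICU_Stays"),
    ),
    "LABEVENTS": (
        LinkRule(("SUBJECT_ID",), "HAS_LAB_EVENTS", "Patient"),
        LinkRule(("HADM_ID",), "HAS_LAB_EVENTS", "Admission"),
        LinkRule(("ITEMID",), "HAS_LAB_ITEM", "Lab_Item", subject_side="row"),
    ),
    "TRANSFERS": (
        LinkRule(("HADM_ID",), "HAS_TRANSFER", "Admission"),
        LinkRule(("ICUSTAY_ID",), "HAS_TRANSFER", "ICU_Stays"),
    ),
    "SERVICES": (LinkRule(("HADM_ID",), "HAS_SERVICE", "Admission"),),
}


def default_mapping(table_name: str, key_echo: bool = True) -> TableMapping:
    """The built-in mapping for one core table."""
    table = registry_table(table_name)
    subject_class = TABLE_CLASS[table.file_name]
    key_cols = tuple(table.primary_key)
    rules = []
    for col in table.columns:
        if not key_echo and col.name in key_cols:
            continue
        rules.append(ColumnRule(col.name, col.name.lower(), col.literal_type))
    return TableMapping(
        table_name=table.file_name,
        subject_class=subject_class,
        subject_key_columns=key_cols,
        column_rules=tuple(rules),
        link_rules=_LINKS.get(table.file_name, ()),
    )


def default_mappings(key_echo: bool = True) -> dict[str, TableMapping]:
    """Mappings for all core tables, keyed by file name."""
    return {name: default_mapping(name, key_echo=key_echo)
            for name in sorted(TABLE_CLASS)}


def _parse_override(name: str, base: TableMapping, spec: Mapping) -> TableMapping:
    column_rules = list(base.column_rules)
    if "drop_columns" in spec:
        drop = {c.upper() for c in spec["drop_columns"]}
        column_rules = [r for r in column_rules if r.column not in drop]
    if "column_rules" in spec:
        column_rules = [
            ColumnRule(r["column"].upper(), r.get("property", r["column"].lower()),
                       r.get("literal_type", "string"))
            for r in spec["column_rules"]
        ]
    link_rules = base.link_rules
    if "link_rules" in spec:
        link_rules = tuple(
            LinkRule(tuple(c.upper() for c in r["columns"]), r["property"],
                     r["target_class"], r.get("subject_side", "target"))
            for r in spec["link_rules"]
        )
    row_filter = base.row_filter
    if "row_filter" in spec:
        f = spec["row_filter"]
        row_filter = (f["column"].upper(), f.get("op", "=="), str(f["value"]))
    return TableMapping(
        table_name=base.table_name,
        subject_class=spec.get("subject_class", base.subject_class),
        subject_key_columns=base.subject_key_columns,
        column_rules=tuple(column_rules),
        link_rules=link_rules,
        row_filter=row_filter,
    )


def load_mappings(overrides_path: Optional[str] = None,
                  key_echo: bool = True) -> dict[str, TableMapping]:
    """Default mappings, optionally patched by a YAML overrides file."""
    mappings = default_mappings(key_echo=key_echo)
    if overrides_path is None:
        return mappings
    spec = yaml.safe_load(Path(overrides_path).read_text()) or {}
    for name, table_spec in spec.items():
        key = name.upper()
        if key not in mappings:
            raise KeyError(f"override for unknown/unmapped table {name!r}")
        mappings[key] = _parse_override(key, mappings[key], table_spec)
    return mappings
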