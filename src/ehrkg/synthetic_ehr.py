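"""Seeded synthetic MIMIC-III-shaped datasets with planted cohorts.

The generator writes referentially consistent CSV tables in the shape
the table registry declares, plants three study cohorts — diabetes
(ICD-9 ``250.x``), hypertension (``401.x``) and patients with multiple
ICU stays — and records the exact planted membership in a ground-truth
manifest so downstream graph queries can be checked against an oracle.

Planting is by exact count (``floor(fraction * n_patients)``), not by
coin flip, so realized cohort sizes are deterministic for every seed.
Background diagnosis codes never share the ``250``/``401`` prefixes and
non-members receive at most one ICU stay, so the planted sets are the
*only* members: manifest, direct CSV scan, and SPARQL must agree exactly.

Each table draws from its own pseudo-random stream derived from
``(seed, table name)``, so adding a table never perturbs another's
content.  Identical specs yield byte-identical files.

Dates live in a far-future window (2100s), mirroring the date-shifting
convention of de-identified ICU records; timestamps are written as
``YYYY-MM-DD HH:MM:SS``.

The values themselves (lab results, doses) are plausible-typed filler,
not clinically calibrated.
"""

from __future__ import annotations

import csv
import json
import zlib
from dataclasses import asdict, dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .ontology import table_registry

_DT_FMT = "%Y-%m-%d %H:%M:%S"


class SpecError(ValueError):
    pass


class FixtureError(ValueError):
    pass


# Background ICD-9 diagnosis pool: deliberately free of the 250/401
# prefixes that define the planted cohorts.
_BACKGROUND_DX = (
    "41401", "486", "5849", "431", "0389", "51881", "4280", "5070",
    "5990", "2859", "42731", "5845", "78552", "99592",
)
_DIABETES_DX = ("25000", "25002", "25060", "25040")
_HYPERTENSION_DX = ("4010", "4011", "4019")
_PROCEDURES = ("3961", "8856", "9904", "3893", "0331", "9671", "3995")
_DRUGS = (
    "Insulin", "Metoprolol", "Furosemide", "Heparin", "Lisinopril",
    "Aspirin", "Vancomycin", "Morphine Sulfate",
)
_LAB_ITEMS = (
    (50912, "Creatinine", "Blood", "Chemistry", "2160-0"),
    (50931, "Glucose", "Blood", "Chemistry", "2345-7"),
    (50971, "Potassium", "Blood", "Chemistry", "2823-3"),
    (50983, "Sodium", "Blood", "Chemistry", "2951-2"),
    (51221, "Hematocrit", "Blood", "Hematology", "4544-3"),
)
_CAREUNITS = ("MICU", "SICU", "CCU", "CSRU", "TSICU")
_SERVICES_LIST = ("MED", "SURG", "CCU", "CMED", "NSURG")
_DX_TITLES = {
    "41401": "Crnry athrscl natve vssl", "486": "Pneumonia organism NOS",
    "5849": "Acute kidney failure NOS", "431": "Intracerebral hemorrhage",
    "0389": "Septicemia NOS", "51881": "Acute respiratry failure",
    "4280": "CHF NOS", "5070": "Food/vomit pneumonitis",
    "5990": "Urin tract infection NOS", "2859": "Anemia NOS",
    "42731": "Atrial fibrillation", "5845": "Ac kidny fail tubr necr",
    "78552": "Septic shock", "99592": "Severe sepsis",
    "25000": "DMII wo cmp nt st uncntr", "25002": "DMII wo cmp uncntrld",
    "25060": "DMII neuro nt st uncntrl", "25040": "DMII renl nt st uncntrld",
    "4010": "Malignant hypertension", "4011": "Benign hypertension",
    "4019": "Hypertension NOS",
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic EHR.

    Cohort fractions are planted by exact count; ``comorbid_fraction``
    must not exceed either single-condition fraction.
    """

    seed: int = 42
    n_patients: int = 100
    date_window: tuple[str, str] = ("2100-01-01 00:00:00", "2105-12-31 00:00:00")
    mean_admissions_per_patient: float = 1.3
    icu_stay_probability: float = 0.7
    diabetes_fraction: float = 0.10
    hypertension_fraction: float = 0.08
    comorbid_fraction: float = 0.03
    multi_icu_fraction: float = 0.10
    genders: tuple[str, ...] = ("M", "F")
    races: tuple[str, ...] = ("WHITE", "BLACK", "ASIAN", "HISPANIC", "OTHER")
    marital_statuses: tuple[str, ...] = ("MARRIED", "SINGLE", "DIVORCED", "WIDOWED")

    def validate(self) -> None:
        fracs = {
            "diabetes_fraction": self.diabetes_fraction,
            "hypertension_fraction": self.hypertension_fraction,
            "comorbid_fraction": self.comorbid_fraction,
            "multi_icu_fraction": self.multi_icu_fraction,
            "icu_stay_probability": self.icu_stay_probability,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must be in [0, 1], got {v}")
        if self.comorbid_fraction > min(self.diabetes_fraction, self.hypertension_fraction):
            raise SpecError("comorbid_fraction exceeds a single-condition fraction")
        if self.n_patients < 0:
            raise SpecError("n_patients must be >= 0")
        if self.mean_admissions_per_patient < 1.0:
            raise SpecError("mean_admissions_per_patient must be >= 1")
        start, end = (datetime.strptime(d, _DT_FMT) for d in self.date_window)
        if start >= end:
            raise SpecError("date_window start must precede end")


@dataclass
class GroundTruthManifest:
    """Exact planted membership of every cohort, plus row counts."""

    seed: int
    n_patients: int
    diabetes: set[int] = field(default_factory=set)
    hypertension: set[int] = field(default_factory=set)
    comorbid: set[int] = field(default_factory=set)
    multi_icu: set[int] = field(default_factory=set)
    multi_icu_counts: dict[int, int] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    spec: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "n_patients": self.n_patients,
            "diabetes": sorted(self.diabetes),
            "hypertension": sorted(self.hypertension),
            "comorbid": sorted(self.comorbid),
            "multi_icu": sorted(self.multi_icu),
            "multi_icu_counts": {str(k): v for k, v in sorted(self.multi_icu_counts.items())},
            "row_counts": dict(sorted(self.row_counts.items())),
            "spec": self.spec,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)
        return cls(
            seed=d["seed"], n_patients=d["n_patients"],
            diabetes=set(d["diabetes"]), hypertension=set(d["hypertension"]),
            comorbid=set(d["comorbid"]), multi_icu=set(d["multi_icu"]),
            multi_icu_counts={int(k): v for k, v in d["multi_icu_counts"].items()},
            row_counts=d["row_counts"], spec=d.get("spec", {}),
        )


def _rng(spec: GeneratorSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed, zlib.crc32(stream.encode())])


def _fmt(dt: datetime) -> str:
    return dt.strftime(_DT_FMT)


def _write_csv(path: Path, header: list[str], rows: Iterable[list]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow(row)


def generate(spec: GeneratorSpec, out_dir) -> GroundTruthManifest:
    """Write the synthetic dataset and return its ground-truth manifest."""
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = spec.n_patients
    window_start, window_end = (datetime.strptime(d, _DT_FMT) for d in spec.date_window)
    span_days = (window_end - window_start).days

    subject_ids = list(range(10001, 10001 + n))

    # -- cohort planting (exact counts) ---------------------------------
    rng_c = _rng(spec, "cohorts")
    n_d = int(spec.diabetes_fraction * n)
    n_h = int(spec.hypertension_fraction * n)
    n_c = int(spec.comorbid_fraction * n)
    n_m = int(spec.multi_icu_fraction * n)
    perm = [subject_ids[i] for i in rng_c.permutation(n)] if n else []
    comorbid = set(perm[:n_c])
    diabetes = comorbid | set(perm[n_c:n_d])
    hypertension = comorbid | set(perm[n_d:n_d + (n_h - n_c)])
    perm2 = [subject_ids[i] for i in rng_c.permutation(n)] if n else []
    multi_icu = set(perm2[:n_m])

    manifest = GroundTruthManifest(
        seed=spec.seed, n_patients=n,
        diabetes=diabetes, hypertension=hypertension,
        comorbid=comorbid, multi_icu=multi_icu,
        spec={k: list(v) if isinstance(v, tuple) else v
              for k, v in asdict(spec).items()},
    )

    # -- PATIENTS --------------------------------------------------------
    rng = _rng(spec, "PATIENTS")
    patients_rows = []
    dob: dict[int, datetime] = {}
    for i, sid in enumerate(subject_ids):
        gender = spec.genders[rng.integers(len(spec.genders))]
        race = spec.races[rng.integers(len(spec.races))]
        marital = spec.marital_statuses[rng.integers(len(spec.marital_statuses))]
        born = window_start - timedelta(days=int(rng.integers(20 * 365, 85 * 365)))
        dob[sid] = born
        expire = int(rng.random() < 0.1)
        dod = _fmt(window_end + timedelta(days=int(rng.integers(1, 300)))) if expire else ""
        patients_rows.append([i + 1, sid, gender, race, marital, _fmt(born), dod, expire])

    # -- ADMISSIONS ------------------------------------------------------
    rng = _rng(spec, "ADMISSIONS")
    admissions: list[dict] = []
    adm_by_patient: dict[int, list[dict]] = {sid: [] for sid in subject_ids}
    hadm_id = 100001
    for sid in subject_ids:
        n_adm = 1 + int(rng.poisson(max(spec.mean_admissions_per_patient - 1.0, 0.0)))
        offsets = sorted(int(o) for o in rng.integers(0, max(span_days - 30, 1), size=n_adm))
        for k, off in enumerate(offsets):
            admit = window_start + timedelta(days=off, hours=int(rng.integers(0, 24)))
            disch = admit + timedelta(days=int(rng.integers(2, 15)), hours=int(rng.integers(0, 24)))
            adm = {
                "SUBJECT_ID": sid, "HADM_ID": hadm_id, "ADMIT": admit, "DISCH": disch,
                "TYPE": ("EMERGENCY", "ELECTIVE", "URGENT")[int(rng.integers(3))],
            }
            admissions.append(adm)
            adm_by_patient[sid].append(adm)
            hadm_id += 1
    admissions_rows = [
        [i + 1, a["SUBJECT_ID"], a["HADM_ID"], _fmt(a["ADMIT"]), _fmt(a["DISCH"]),
         a["TYPE"], "EMERGENCY ROOM ADMIT", "Medicare", "ADMISSION NOTE", 0]
        for i, a in enumerate(admissions)
    ]

    # -- ICUSTAYS --------------------------------------------------------
    # Non-members get at most one stay so the multi-ICU cohort is exact.
    rng = _rng(spec, "ICUSTAYS")
    icustays: list[dict] = []
    icustay_id = 200001
    for sid in subject_ids:
        adms = adm_by_patient[sid]
        if sid in multi_icu:
            n_stay = 2 + int(rng.integers(0, 2))
        else:
            n_stay = int(rng.random() < spec.icu_stay_probability)
        for _ in range(n_stay):
            adm = adms[int(rng.integers(len(adms)))]
            total_h = int((adm["DISCH"] - adm["ADMIT"]).total_seconds() // 3600)
            start_h = int(rng.integers(0, max(total_h - 24, 1)))
            intime = adm["ADMIT"] + timedelta(hours=start_h)
            dur_h = int(rng.integers(12, min(max(total_h - start_h, 13), 24 * 7)))
            outtime = intime + timedelta(hours=dur_h)
            unit = _CAREUNITS[int(rng.integers(len(_CAREUNITS)))]
            icustays.append({
                "SUBJECT_ID": sid, "HADM_ID": adm["HADM_ID"], "ICUSTAY_ID": icustay_id,
                "UNIT": unit, "INTIME": intime, "OUTTIME": outtime,
                "LOS": round(dur_h / 24.0, 4),
            })
            icustay_id += 1
    icustays.sort(key=lambda s: s["ICUSTAY_ID"])
    icustays_rows = [
        [i + 1, s["SUBJECT_ID"], s["HADM_ID"], s["ICUSTAY_ID"], s["UNIT"], s["UNIT"],
         _fmt(s["INTIME"]), _fmt(s["OUTTIME"]), f"{s['LOS']:.4f}"]
        for i, s in enumerate(icustays)
    ]
    stays_by_hadm: dict[int, list[dict]] = {}
    for s in icustays:
        stays_by_hadm.setdefault(s["HADM_ID"], []).append(s)
    for sid in multi_icu:
        manifest.multi_icu_counts[sid] = sum(
            1 for s in icustays if s["SUBJECT_ID"] == sid)

    # -- DIAGNOSES_ICD ---------------------------------------------------
    rng = _rng(spec, "DIAGNOSES_ICD")
    dx_rows = []
    row_id = 1
    for sid in subject_ids:
        adms = adm_by_patient[sid]
        codes_by_adm: dict[int, list[str]] = {a["HADM_ID"]: [] for a in adms}
        for a in adms:
            for _ in range(1 + int(rng.integers(0, 3))):
                codes_by_adm[a["HADM_ID"]].append(
                    _BACKGROUND_DX[int(rng.integers(len(_BACKGROUND_DX)))])
        if sid in diabetes:
            a = adms[int(rng.integers(len(adms)))]
            codes_by_adm[a["HADM_ID"]].append(
                _DIABETES_DX[int(rng.integers(len(_DIABETES_DX)))])
        if sid in hypertension:
            a = adms[int(rng.integers(len(adms)))]
            codes_by_adm[a["HADM_ID"]].append(
                _HYPERTENSION_DX[int(rng.integers(len(_HYPERTENSION_DX)))])
        for a in adms:
            for seq, code in enumerate(codes_by_adm[a["HADM_ID"]], start=1):
                dx_rows.append([row_id, sid, a["HADM_ID"], seq, code])
                row_id += 1

    # -- PROCEDURES_ICD --------------------------------------------------
    rng = _rng(spec, "PROCEDURES_ICD")
    proc_rows = []
    row_id = 1
    for a in admissions:
        for seq in range(1, 1 + int(rng.integers(0, 3))):
            proc_rows.append([row_id, a["SUBJECT_ID"], a["HADM_ID"], seq,
                              _PROCEDURES[int(rng.integers(len(_PROCEDURES)))]])
            row_id += 1

    # -- PRESCRIPTIONS ---------------------------------------------------
    rng = _rng(spec, "PRESCRIPTIONS")
    rx_rows = []
    row_id = 1
    for a in admissions:
        stays = stays_by_hadm.get(a["HADM_ID"], [])
        for _ in range(1 + int(rng.integers(0, 3))):
            start = a["ADMIT"] + timedelta(hours=int(rng.integers(0, 48)))
            end = start + timedelta(days=int(rng.integers(1, 5)))
            icustay = ""
            if stays and rng.random() < 0.5:
                icustay = stays[int(rng.integers(len(stays)))]["ICUSTAY_ID"]
            drug = _DRUGS[int(rng.integers(len(_DRUGS)))]
            dose = int(rng.integers(1, 100))
            rx_rows.append([row_id, a["SUBJECT_ID"], a["HADM_ID"], icustay,
                            _fmt(start), _fmt(end), "MAIN", drug, dose, "mg", "IV"])
            row_id += 1

    # -- LABEVENTS -------------------------------------------------------
    rng = _rng(spec, "LABEVENTS")
    lab_rows = []
    row_id = 1
    for a in admissions:
        for _ in range(2):
            item = _LAB_ITEMS[int(rng.integers(len(_LAB_ITEMS)))]
            when = a["ADMIT"] + timedelta(hours=int(rng.integers(1, 72)))
            value = round(float(rng.uniform(0.5, 150.0)), 1)
            flag = "abnormal" if rng.random() < 0.2 else ""
            lab_rows.append([row_id, a["SUBJECT_ID"], a["HADM_ID"], item[0],
                             _fmt(when), value, value, "mg/dL", flag])
            row_id += 1

    # -- dictionaries and staff (header-only for an empty population) ----
    d_labitems_rows: list[list] = []
    d_icd_rows: list[list] = []
    caregivers_rows: list[list] = []
    if n > 0:
        d_labitems_rows = [[i + 1, *item] for i, item in enumerate(_LAB_ITEMS)]
        all_codes = sorted(set(_BACKGROUND_DX) | set(_DIABETES_DX) | set(_HYPERTENSION_DX))
        d_icd_rows = [[i + 1, code, _DX_TITLES[code], _DX_TITLES[code]]
                      for i, code in enumerate(all_codes)]
        rng = _rng(spec, "CAREGIVERS")
        caregivers_rows = [
            [i + 1, str(16170 + i), ("RN", "MD", "RT")[int(rng.integers(3))],
             "ICU staff"] for i in range(10)
        ]

    # -- TRANSFERS / SERVICES / CALLOUT ---------------------------------
    rng = _rng(spec, "TRANSFERS")
    transfer_rows = []
    row_id = 1
    for a in admissions:
        transfer_rows.append([row_id, a["SUBJECT_ID"], a["HADM_ID"], "", "admit",
                              "", "EW", _fmt(a["ADMIT"]), _fmt(a["ADMIT"] + timedelta(hours=2))])
        row_id += 1
        for s in stays_by_hadm.get(a["HADM_ID"], []):
            transfer_rows.append([row_id, a["SUBJECT_ID"], a["HADM_ID"], s["ICUSTAY_ID"],
                                  "transfer", "EW", s["UNIT"], _fmt(s["INTIME"]),
                                  _fmt(s["OUTTIME"])])
            row_id += 1

    rng = _rng(spec, "SERVICES")
    services_rows = [
        [i + 1, a["SUBJECT_ID"], a["HADM_ID"], _fmt(a["ADMIT"]), "",
         _SERVICES_LIST[int(rng.integers(len(_SERVICES_LIST)))]]
        for i, a in enumerate(admissions)
    ]

    rng = _rng(spec, "CALLOUT")
    callout_rows = []
    row_id = 1
    for a in admissions:
        if rng.random() < 0.3:
            create = a["DISCH"] - timedelta(days=1)
            callout_rows.append([row_id, a["SUBJECT_ID"], a["HADM_ID"],
                                 int(rng.integers(1, 60)), "MED", "Discharged",
                                 _fmt(create), _fmt(a["DISCH"])])
            row_id += 1

    # -- write everything ------------------------------------------------
    tables = {
        "PATIENTS": patients_rows, "ADMISSIONS": admissions_rows,
        "ICUSTAYS": icustays_rows, "DIAGNOSES_ICD": dx_rows,
        "PROCEDURES_ICD": proc_rows, "PRESCRIPTIONS": rx_rows,
        "LABEVENTS": lab_rows, "D_LABITEMS": d_labitems_rows,
        "D_ICD_DIAGNOSES": d_icd_rows, "CAREGIVERS": caregivers_rows,
        "TRANSFERS": transfer_rows, "SERVICES": services_rows,
        "CALLOUT": callout_rows,
    }
    for table in table_registry():
        name = table.file_name
        rows = tables.get(name, [])
        _write_csv(out / f"{name}.csv", table.column_names(), rows)
        manifest.row_counts[name] = len(rows)
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Independent oracle: direct CSV scans, no RDF involved
# ---------------------------------------------------------------------------

def oracle_scan(data_dir, cohort_kind: str, params: Optional[Mapping] = None) -> set[int]:
    """Recompute a cohort straight from the CSV files.

    Supported kinds: ``diagnosis_prefix`` (params: ``prefix``),
    ``comorbid`` (params: ``prefix_a``, ``prefix_b``), ``multi_icu``
    (params: ``min_stays``).
    """
    params = dict(params or {})
    data_dir = Path(data_dir)
    if cohort_kind == "diagnosis_prefix":
        return _scan_dx_prefix(data_dir, params.get("prefix", "250"))
    if cohort_kind == "comorbid":
        return (_scan_dx_prefix(data_dir, params.get("prefix_a", "401"))
                & _scan_dx_prefix(data_dir, params.get("prefix_b", "250")))
    if cohort_kind == "multi_icu":
        return set(multi_icu_counts(data_dir, params.get("min_stays", 2)))
    raise ValueError(f"unknown cohort kind {cohort_kind!r}")


def _read_table(data_dir: Path, name: str) -> pd.DataFrame:
    path = data_dir / f"{name}.csv"
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _scan_dx_prefix(data_dir: Path, prefix: str) -> set[int]:
    dx = _read_table(data_dir, "DIAGNOSES_ICD")
    hit = dx[dx["ICD9_CODE"].str.startswith(prefix)]
    return set(hit["SUBJECT_ID"].astype(int))


def multi_icu_counts(data_dir, min_stays: int = 2) -> dict[int, int]:
    """Distinct ICU-stay counts per patient, restricted to >= min_stays."""
    stays = _read_table(Path(data_dir), "ICUSTAYS")
    if stays.empty:
        return {}
    counts = stays.groupby("SUBJECT_ID")["ICUSTAY_ID"].nunique()
    return {int(sid): int(c) for sid, c in counts.items() if c >= min_stays}


# ---------------------------------------------------------------------------
# Integrity checking and defect injection
# ---------------------------------------------------------------------------

_FK_CHECKS = (
    ("ADMISSIONS", "SUBJECT_ID", "PATIENTS", "SUBJECT_ID"),
    ("ICUSTAYS", "HADM_ID", "ADMISSIONS", "HADM_ID"),
    ("ICUSTAYS", "SUBJECT_ID", "PATIENTS", "SUBJECT_ID"),
    ("DIAGNOSES_ICD", "HADM_ID", "ADMISSIONS", "HADM_ID"),
    ("PROCEDURES_ICD", "HADM_ID", "ADMISSIONS", "HADM_ID"),
    ("PRESCRIPTIONS", "HADM_ID", "ADMISSIONS", "HADM_ID"),
    ("LABEVENTS", "HADM_ID", "ADMISSIONS", "HADM_ID"),
)
_DATE_ORDER_CHECKS = (
    ("ADMISSIONS", "ADMITTIME", "DISCHTIME"),
    ("ICUSTAYS", "INTIME", "OUTTIME"),
    ("TRANSFERS", "INTIME", "OUTTIME"),
)


def check_integrity(data_dir) -> list[dict]:
    """Referential-integrity and date-ordering violations, as data."""
    data_dir = Path(data_dir)
    violations: list[dict] = []
    cache: dict[str, pd.DataFrame] = {}

    def table(name: str) -> pd.DataFrame:
        if name not in cache:
            cache[name] = _read_table(data_dir, name)
        return cache[name]

    for child, col, parent, pcol in _FK_CHECKS:
        df = table(child)
        if df.empty:
            continue
        valid = set(table(parent)[pcol])
        bad = df[(df[col] != "") & ~df[col].isin(valid)]
        for idx in bad.index:
            violations.append({"code": "ORPHAN_FK", "table": child,
                               "column": col, "row": int(idx),
                               "value": bad.loc[idx, col]})
    for name, start_col, end_col in _DATE_ORDER_CHECKS:
        df = table(name)
        if df.empty:
            continue
        both = df[(df[start_col] != "") & (df[end_col] != "")]
        bad = both[both[start_col] > both[end_col]]  # lexicographic == temporal here
        for idx in bad.index:
            violations.append({"code": "BAD_DATE_ORDER", "table": name,
                               "column": start_col, "row": int(idx),
                               "value": bad.loc[idx, start_col]})
    # DOB must precede the first admission.
    pats = table("PATIENTS")
    adms = table("ADMISSIONS")
    if not pats.empty and not adms.empty:
        first_admit = adms.groupby("SUBJECT_ID")["ADMITTIME"].min()
        merged = pats.set_index("SUBJECT_ID").join(first_admit, how="inner")
        bad = merged[merged["DOB"] >= merged["ADMITTIME"]]
        for sid in bad.index:
            violations.append({"code": "DOB_AFTER_ADMIT", "table": "PATIENTS",
                               "column": "DOB", "row": -1, "value": str(sid)})
    return violations


def perturb(data_dir, kind: str, seed: int = 0) -> dict:
    """Inject exactly one defect of the given kind; return its coordinates.

    Kinds: ``orphan_fk`` (ADMISSIONS row pointed at a nonexistent
    patient), ``bad_date_order`` (ADMITTIME/DISCHTIME swapped),
    ``duplicate_row`` (a DIAGNOSES_ICD row appended verbatim).
    """
    data_dir = Path(data_dir)
    rng = np.random.default_rng(seed)

    def load(name: str) -> tuple[list[str], list[list[str]]]:
        with open(data_dir / f"{name}.csv", newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        if len(rows) < 2:
            raise FixtureError(f"{name} has no data rows to perturb")
        return rows[0], rows[1:]

    def save(name: str, header: list[str], rows: list[list[str]]) -> None:
        _write_csv(data_dir / f"{name}.csv", header, rows)

    if kind == "orphan_fk":
        header, rows = load("ADMISSIONS")
        i = int(rng.integers(len(rows)))
        col = header.index("SUBJECT_ID")
        new_value = str(max(int(r[col]) for r in rows) + 999983)
        rows[i][col] = new_value
        save("ADMISSIONS", header, rows)
        return {"kind": kind, "table": "ADMISSIONS", "row": i,
                "column": "SUBJECT_ID", "value": new_value}
    if kind == "bad_date_order":
        header, rows = load("ADMISSIONS")
        i = int(rng.integers(len(rows)))
        a, d = header.index("ADMITTIME"), header.index("DISCHTIME")
        if rows[i][a] == rows[i][d]:
            raise FixtureError("cannot invert identical timestamps")
        rows[i][a], rows[i][d] = rows[i][d], rows[i][a]
        save("ADMISSIONS", header, rows)
        return {"kind": kind, "table": "ADMISSIONS", "row": i,
                "column": "ADMITTIME", "value": rows[i][a]}
    if kind == "duplicate_row":
        header, rows = load("DIAGNOSES_ICD")
        i = int(rng.integers(len(rows)))
        rows.append(list(rows[i]))
        save("DIAGNOSES_ICD", header, rows)
        return {"kind": kind, "table": "DIAGNOSES_ICD", "row": i,
                "column": None, "value": None}
    raise ValueError(f"unknown perturbation kind {kind!r}")
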