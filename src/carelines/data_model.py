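"""Canonical record types and CSV readers/writers for the six claims tables.

The pipeline consumes six delimited tables emulating the longitudinal
databases of a health-maintenance organisation: patient demographics and
vital status, pharmacy dispensing records, infusion claims, surgery claims,
laboratory results, and a drug dictionary mapping opaque drug codes to
oncology agent classes or non-oncology medication categories.

All dates are day-resolution calendar dates (ISO-8601 in files); every
interval elsewhere in the package is half-open ``[start, end)`` in days.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

# --- vocabulary -----------------------------------------------------------

ONCOLOGY_AGENT_CLASSES = frozenset(
    {"FP_oral", "FP_iv", "oxaliplatin", "irinotecan",
     "bevacizumab", "cetuximab", "panitumumab"}
)
FP_CLASSES = frozenset({"FP_oral", "FP_iv"})
BIOLOGIC_CLASSES = frozenset({"bevacizumab", "cetuximab", "panitumumab"})
ANTI_EGFR_CLASSES = frozenset({"cetuximab", "panitumumab"})
AGENT_CLASSES = ONCOLOGY_AGENT_CLASSES | {"non_oncology"}

NON_ONCOLOGY_CATEGORIES = frozenset(
    {"narcotic", "corticosteroid", "diuretic", "gi_ppi", "antiemetic", "other"}
)
REGISTRY_FLAGS = ("diabetes", "hypertension", "cvd")
SURGERY_PROCEDURES = frozenset(
    {"liver_metastasectomy", "lung_metastasectomy", "definitive_rt", "other"}
)
LAB_TESTS = frozenset(
    {"platelets", "leukocytes", "cholesterol", "ldl", "urine_protein", "cea"}
)


# --- record types ---------------------------------------------------------

@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: str                       # "male" | "female"
    birth_date: dt.date
    death_date: dt.date | None
    last_seen_date: dt.date
    registry_flags: frozenset[str] = frozenset()

    def alive_at(self, day: dt.date) -> bool:
        return self.death_date is None or self.death_date > day


@dataclass(frozen=True)
class DispenseEvent:
    patient_id: str
    date: dt.date
    drug_code: str


@dataclass(frozen=True)
class InfusionEvent:
    patient_id: str
    date: dt.date
    agent_code: str


@dataclass(frozen=True)
class SurgeryClaim:
    patient_id: str
    date: dt.date
    procedure: str


@dataclass(frozen=True)
class LabResult:
    patient_id: str
    date: dt.date
    test: str
    value: float


@dataclass(frozen=True)
class DrugDictionary:
    """Total map ``drug_code -> (agent_class, category)``.

    ``agent_class`` is one of the oncology classes or ``non_oncology``;
    ``category`` is meaningful for non-oncology codes only.
    """

    mapping: dict[str, tuple[str, str]]

    def agent_class(self, code: str) -> str | None:
        entry = self.mapping.get(code)
        return entry[0] if entry else None

    def category(self, code: str) -> str | None:
        entry = self.mapping.get(code)
        return entry[1] if entry else None

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, code: str) -> bool:
        return code in self.mapping


# --- diagnostics ----------------------------------------------------------

@dataclass(frozen=True)
class RowDiagnostic:
    """A row-level parse or invariant failure; ``line`` is 1-based in-file."""

    line: int
    message: str


class SchemaError(ValueError):
    """Header does not match the declared table schema."""


class DictionaryError(ValueError):
    """Drug dictionary contains conflicting duplicate mappings."""


@dataclass
class TableReadResult:
    records: list
    diagnostics: list[RowDiagnostic] = field(default_factory=list)


# --- schemas --------------------------------------------------------------

SCHEMAS: dict[str, list[str]] = {
    "patients": ["patient_id", "sex", "birth_date", "death_date",
                 "last_seen_date", "diabetes", "hypertension", "cvd"],
    "dispenses": ["patient_id", "date", "drug_code"],
    "infusions": ["patient_id", "date", "agent_code"],
    "surgeries": ["patient_id", "date", "procedure"],
    "labs": ["patient_id", "date", "test", "value"],
    "drug_dict": ["drug_code", "agent_class", "category"],
}


def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(text.strip())


def _parse_optional_date(text: str) -> dt.date | None:
    text = text.strip()
    return None if text == "" else dt.date.fromisoformat(text)


def _parse_flag(text: str) -> bool:
    return text.strip() in {"1", "true", "True", "yes"}


def _row_to_patient(row: dict[str, str]) -> Patient:
    p = Patient(
        patient_id=row["patient_id"],
        sex=row["sex"],
        birth_date=_parse_date(row["birth_date"]),
        death_date=_parse_optional_date(row["death_date"]),
        last_seen_date=_parse_date(row["last_seen_date"]),
        registry_flags=frozenset(f for f in REGISTRY_FLAGS if _parse_flag(row[f])),
    )
    if p.sex not in {"male", "female"}:
        raise ValueError(f"unknown sex {p.sex!r}")
    if p.death_date is not None and p.death_date < p.birth_date:
        raise ValueError("death_date precedes birth_date")
    if p.last_seen_date < p.birth_date:
        raise ValueError("last_seen_date precedes birth_date")
    return p


def _row_to_surgery(row: dict[str, str]) -> SurgeryClaim:
    proc = row["procedure"].strip()
    if proc not in SURGERY_PROCEDURES:
        raise ValueError(f"unknown procedure {proc!r}")
    return SurgeryClaim(row["patient_id"], _parse_date(row["date"]), proc)


def _row_to_lab(row: dict[str, str]) -> LabResult:
    value = float(row["value"])
    if value != value or value in (float("inf"), float("-inf")):
        raise ValueError("lab value not finite")
    return LabResult(row["patient_id"], _parse_date(row["date"]),
                     row["test"].strip(), value)


_ROW_PARSERS = {
    "patients": _row_to_patient,
    "dispenses": lambda r: DispenseEvent(r["patient_id"], _parse_date(r["date"]),
                                         r["drug_code"].strip()),
    "infusions": lambda r: InfusionEvent(r["patient_id"], _parse_date(r["date"]),
                                         r["agent_code"].strip()),
    "surgeries": _row_to_surgery,
    "labs": _row_to_lab,
}


def read_table(path: str | Path, schema_name: str) -> TableReadResult:
    """Read one claims table, returning typed records plus row diagnostics.

    Rows that violate the schema's field types or record invariants are
    rejected individually; the rest of the file still parses.  A missing
    column raises :class:`SchemaError` naming the column.
    """
    if schema_name not in SCHEMAS or schema_name == "drug_dict":
        raise ValueError(f"unknown table schema {schema_name!r}")
    expected = SCHEMAS[schema_name]
    parser = _ROW_PARSERS[schema_name]
    records: list = []
    diagnostics: list[RowDiagnostic] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in expected if c not in header]
        if missing:
            raise SchemaError(
                f"{Path(path).name}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(parser(row))
            except (ValueError, KeyError, TypeError) as exc:
                diagnostics.append(RowDiagnostic(lineno, str(exc)))
    return TableReadResult(records, diagnostics)


def write_table(records: Sequence, path: str | Path, schema_name: str) -> None:
    """Write typed records back to CSV (inverse of :func:`read_table`)."""
    cols = SCHEMAS[schema_name]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in records:
            if schema_name == "patients":
                writer.writerow([
                    rec.patient_id, rec.sex, rec.birth_date.isoformat(),
                    rec.death_date.isoformat() if rec.death_date else "",
                    rec.last_seen_date.isoformat(),
                    *(int(f in rec.registry_flags) for f in REGISTRY_FLAGS),
                ])
            elif schema_name == "dispenses":
                writer.writerow([rec.patient_id, rec.date.isoformat(), rec.drug_code])
            elif schema_name == "infusions":
                writer.writerow([rec.patient_id, rec.date.isoformat(), rec.agent_code])
            elif schema_name == "surgeries":
                writer.writerow([rec.patient_id, rec.date.isoformat(), rec.procedure])
            elif schema_name == "labs":
                writer.writerow([rec.patient_id, rec.date.isoformat(),
                                 rec.test, repr(rec.value)])
            else:
                raise ValueError(f"unknown table schema {schema_name!r}")


def load_dictionary(path: str | Path) -> DrugDictionary:
    """Load the drug dictionary CSV (``drug_code, agent_class, category``).

    Duplicate codes with the identical mapping collapse to one entry;
    duplicates with conflicting mappings raise :class:`DictionaryError`.
    """
    mapping: dict[str, tuple[str, str]] = {}
    conflicts: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in SCHEMAS["drug_dict"] if c not in header]
        if missing:
            raise SchemaError(
                f"{Path(path).name}: missing column(s) {', '.join(missing)}")
        for row in reader:
            code = row["drug_code"].strip()
            agent_class = row["agent_class"].strip()
            category = row["category"].strip() or "other"
            if agent_class not in AGENT_CLASSES:
                raise DictionaryError(f"unknown agent_class {agent_class!r} "
                                      f"for code {code!r}")
            if agent_class != "non_oncology":
                category = "other"
            entry = (agent_class, category)
            if code in mapping and mapping[code] != entry:
                conflicts.append(code)
            mapping[code] = entry
    if conflicts:
        raise DictionaryError(
            "conflicting duplicate mapping for code(s): " + ", ".join(sorted(set(conflicts))))
    return DrugDictionary(mapping)


def packaged_dictionary() -> DrugDictionary:
    """The editable synthetic drug dictionary shipped with the package.

    Codes are synthetic ATC-like strings; real deployments supply their own
    mapping file with the same three columns.
    """
    from importlib.resources import files

    return load_dictionary(str(files("carelines").joinpath("data/drug_dict.csv")))


def write_dictionary(dictionary: DrugDictionary, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCHEMAS["drug_dict"])
        for code, (agent_class, category) in sorted(dictionary.mapping.items()):
            writer.writerow([code, agent_class, category])


# --- cross-table validation ----------------------------------------------

@dataclass
class ValidationReport:
    """Cross-table consistency findings; records are flagged, never dropped."""

    unknown_patient_rows: dict[str, list[int]] = field(default_factory=dict)
    post_death_rows: dict[str, list[int]] = field(default_factory=dict)
    duplicate_rows: dict[str, list[int]] = field(default_factory=dict)

    def n_flagged(self) -> int:
        return sum(len(v) for d in (self.unknown_patient_rows,
                                    self.post_death_rows,
                                    self.duplicate_rows) for v in d.values())


def validate_tables(patients: Iterable[Patient],
                    tables: dict[str, Sequence]) -> ValidationReport:
    """Flag records with unknown patient_ids, events after death, and exact
    duplicate rows.  Indices reported are 0-based positions in each list."""
    known = {p.patient_id: p for p in patients}
    report = ValidationReport()
    for name, records in tables.items():
        seen: set = set()
        unknown: list[int] = []
        post_death: list[int] = []
        dupes: list[int] = []
        for i, rec in enumerate(records):
            key = rec  # frozen dataclasses hash by value
            if key in seen:
                dupes.append(i)
            seen.add(key)
            pat = known.get(rec.patient_id)
            if pat is None:
                unknown.append(i)
                continue
            date = getattr(rec, "date", None)
            if date is not None and pat.death_date is not None and date > pat.death_date:
                post_death.append(i)
        if unknown:
            report.unknown_patient_rows[name] = unknown
        if post_death:
            report.post_death_rows[name] = post_death
        if dupes:
            report.duplicate_rows[name] = dupes
    return report
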