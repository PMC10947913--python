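"""Domain types for EHR-style inputs and flat-file readers/writers.

The package operates on a small relational snapshot of an electronic
health record: a patient roster, diagnosis records (encounter ICD codes
and problem-list entries), free-text imaging reports, structured
single-value LVEF entries from a catheterization-lab registry,
medication orders, admissions, and specialty encounters.

On disk a cohort is one directory with one CSV per structured record
type plus a JSON-lines file for imaging reports (free text with embedded
newlines survives JSON encoding, which CSV quoting makes fragile).
All dates are ISO-8601 calendar dates; the pipeline operates at day
resolution.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

__all__ = [
    "Patient",
    "DiagnosisRecord",
    "ImagingReport",
    "CartRecord",
    "MedicationRecord",
    "AdmissionRecord",
    "EncounterRecord",
    "Cohort",
    "CohortError",
    "read_cohort",
    "write_cohort",
]

CODE_SYSTEMS = ("ICD9", "ICD10")
DIAGNOSIS_ORIGINS = ("encounter", "problem_list")
IMAGING_SOURCES = ("echo", "clinical_note", "radiology")
MODALITY_HINTS = ("TTE", "TEE", "nuclear", "other")
CART_MODALITIES = ("TTE", "TEE", "MRI", "CT", "ventriculography", "nuclear")


class CohortError(ValueError):
    """Raised for malformed or referentially inconsistent cohort files."""


def _parse_date(value: str, *, context: str) -> date:
    try:
        return date.fromisoformat(value)
    except ValueError as exc:
        raise CohortError(f"{context}: unparseable date {value!r} (expected YYYY-MM-DD)") from exc


def _parse_bool(value: str, *, context: str) -> bool:
    low = value.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise CohortError(f"{context}: unparseable boolean {value!r}")


@dataclass(frozen=True)
class Patient:
    """A roster entry with its reporting hierarchy (provider within facility within network)."""

    patient_id: str
    facility_id: str
    provider_id: str
    network_id: str

    def __post_init__(self) -> None:
        for name in ("patient_id", "facility_id", "provider_id", "network_id"):
            if not getattr(self, name):
                raise CohortError(f"Patient field {name} must be non-empty")


@dataclass(frozen=True)
class DiagnosisRecord:
    """One coded diagnosis, from an encounter or from the problem list.

    ``active`` is meaningful only for problem-list entries: an active
    heart-failure problem-list entry qualifies a patient for inclusion
    even without encounter codes.
    """

    patient_id: str
    code: str
    code_system: str
    record_date: date
    origin: str
    active: bool = False

    def __post_init__(self) -> None:
        if not self.code:
            raise CohortError("DiagnosisRecord.code must be non-empty")
        if self.code_system not in CODE_SYSTEMS:
            raise CohortError(f"unknown code_system {self.code_system!r}")
        if self.origin not in DIAGNOSIS_ORIGINS:
            raise CohortError(f"unknown diagnosis origin {self.origin!r}")


@dataclass(frozen=True)
class ImagingReport:
    """A free-text report that may state one or more ejection fractions."""

    report_id: str
    patient_id: str
    report_date: date
    source_system: str
    modality_hint: str | None
    text: str

    def __post_init__(self) -> None:
        if self.source_system not in IMAGING_SOURCES:
            raise CohortError(f"unknown source_system {self.source_system!r}")
        if self.modality_hint is not None and self.modality_hint not in MODALITY_HINTS:
            raise CohortError(f"unknown modality_hint {self.modality_hint!r}")


@dataclass(frozen=True)
class CartRecord:
    """A structured registry entry: exactly one LVEF with a clinician-entered source modality."""

    patient_id: str
    record_date: date
    lvef: float
    source_modality: str

    def __post_init__(self) -> None:
        if not (0 < self.lvef <= 100):
            raise CohortError(f"CartRecord.lvef {self.lvef} outside (0, 100]")
        if self.source_modality not in CART_MODALITIES:
            raise CohortError(f"unknown CART source_modality {self.source_modality!r}")


@dataclass(frozen=True)
class MedicationRecord:
    """An order interval for one drug; ``end_date`` None means still active."""

    patient_id: str
    drug_name: str
    dose: float
    dose_unit: str
    start_date: date
    end_date: date | None = None

    def __post_init__(self) -> None:
        if self.end_date is not None and self.start_date > self.end_date:
            raise CohortError("MedicationRecord interval start after end")

    def active_on(self, day: date) -> bool:
        return self.start_date <= day and (self.end_date is None or day <= self.end_date)


@dataclass(frozen=True)
class AdmissionRecord:
    patient_id: str
    admit_date: date
    primary_dx_is_hf: bool


@dataclass(frozen=True)
class EncounterRecord:
    patient_id: str
    encounter_date: date
    specialty: str


@dataclass
class Cohort:
    """All tables of one cohort, with referential integrity to the roster."""

    patients: list[Patient] = field(default_factory=list)
    diagnoses: list[DiagnosisRecord] = field(default_factory=list)
    imaging_reports: list[ImagingReport] = field(default_factory=list)
    cart_records: list[CartRecord] = field(default_factory=list)
    medications: list[MedicationRecord] = field(default_factory=list)
    admissions: list[AdmissionRecord] = field(default_factory=list)
    encounters: list[EncounterRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()
        self._normalize()

    def _normalize(self) -> None:
        """Sort every table into canonical order so equality and writes are stable."""
        self.patients.sort(key=lambda p: p.patient_id)
        self.diagnoses.sort(key=lambda r: (r.patient_id, r.record_date, r.code, r.origin))
        self.imaging_reports.sort(key=lambda r: (r.patient_id, r.report_date, r.report_id))
        self.cart_records.sort(key=lambda r: (r.patient_id, r.record_date, r.lvef))
        self.medications.sort(
            key=lambda r: (r.patient_id, r.start_date, r.drug_name,
                           r.end_date or date.max))
        self.admissions.sort(key=lambda r: (r.patient_id, r.admit_date, r.primary_dx_is_hf))
        self.encounters.sort(key=lambda r: (r.patient_id, r.encounter_date, r.specialty))

    def validate(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient_id(s) in roster: {dupes}")
        known = set(ids)
        offending: list[str] = []
        for table_name in ("diagnoses", "imaging_reports", "cart_records",
                           "medications", "admissions", "encounters"):
            for i, rec in enumerate(getattr(self, table_name)):
                if rec.patient_id not in known:
                    offending.append(f"{table_name} row {i}: unknown patient_id {rec.patient_id!r}")
        if offending:
            raise CohortError("referential integrity violated:\n" + "\n".join(offending))

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def for_patient(self, patient_id: str, table: str) -> list:
        return [r for r in getattr(self, table) if r.patient_id == patient_id]


# ---------------------------------------------------------------------------
# File layout

_FILES = {
    "patients": "roster.csv",
    "diagnoses": "diagnoses.csv",
    "cart_records": "cart.csv",
    "medications": "medications.csv",
    "admissions": "admissions.csv",
    "encounters": "encounters.csv",
    "imaging_reports": "imaging_reports.jsonl",
}

_CSV_COLUMNS = {
    "patients": ("patient_id", "facility_id", "provider_id", "network_id"),
    "diagnoses": ("patient_id", "code", "code_system", "record_date", "origin", "active"),
    "cart_records": ("patient_id", "record_date", "lvef", "source_modality"),
    "medications": ("patient_id", "drug_name", "dose", "dose_unit", "start_date", "end_date"),
    "admissions": ("patient_id", "admit_date", "primary_dx_is_hf"),
    "encounters": ("patient_id", "encounter_date", "specialty"),
}


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, date):
        return value.isoformat()
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write a cohort to ``directory`` deterministically.

    Rows are sorted by all columns in order (patient_id first, dates
    next), so write -> read -> write is byte-identical.
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    for table, filename in _FILES.items():
        records = getattr(cohort, table)
        path = out / filename
        if table == "imaging_reports":
            rows = sorted(
                records, key=lambda r: (r.patient_id, r.report_date, r.report_id)
            )
            with path.open("w", encoding="utf-8", newline="\n") as fh:
                for r in rows:
                    fh.write(json.dumps({
                        "report_id": r.report_id,
                        "patient_id": r.patient_id,
                        "report_date": r.report_date.isoformat(),
                        "source_system": r.source_system,
                        "modality_hint": r.modality_hint,
                        "text": r.text,
                    }, sort_keys=False) + "\n")
            continue
        columns = _CSV_COLUMNS[table]
        str_rows = sorted(
            tuple(_cell(getattr(r, c)) for c in columns) for r in records
        )
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
            writer.writerow(columns)
            writer.writerows(str_rows)


def _row_to_record(table: str, row: dict[str, str], context: str):
    if table == "patients":
        return Patient(row["patient_id"], row["facility_id"], row["provider_id"], row["network_id"])
    if table == "diagnoses":
        return DiagnosisRecord(
            patient_id=row["patient_id"],
            code=row["code"],
            code_system=row["code_system"],
            record_date=_parse_date(row["record_date"], context=context),
            origin=row["origin"],
            active=_parse_bool(row["active"], context=context),
        )
    if table == "cart_records":
        return CartRecord(
            patient_id=row["patient_id"],
            record_date=_parse_date(row["record_date"], context=context),
            lvef=float(row["lvef"]),
            source_modality=row["source_modality"],
        )
    if table == "medications":
        return MedicationRecord(
            patient_id=row["patient_id"],
            drug_name=row["drug_name"],
            dose=float(row["dose"]),
            dose_unit=row["dose_unit"],
            start_date=_parse_date(row["start_date"], context=context),
            end_date=None if row["end_date"] == "" else _parse_date(row["end_date"], context=context),
        )
    if table == "admissions":
        return AdmissionRecord(
            patient_id=row["patient_id"],
            admit_date=_parse_date(row["admit_date"], context=context),
            primary_dx_is_hf=_parse_bool(row["primary_dx_is_hf"], context=context),
        )
    if table == "encounters":
        return EncounterRecord(
            patient_id=row["patient_id"],
            encounter_date=_parse_date(row["encounter_date"], context=context),
            specialty=row["specialty"],
        )
    raise AssertionError(table)


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`.

    Missing files are fatal; rows referencing patients absent from the
    roster raise a :class:`CohortError` listing the offending rows.
    """
    base = Path(directory)
    tables: dict[str, list] = {}
    for table, filename in _FILES.items():
        path = base / filename
        if not path.exists():
            raise CohortError(f"missing cohort file: {path}")
        if table == "imaging_reports":
            reports: list[ImagingReport] = []
            with path.open(encoding="utf-8") as fh:
                for lineno, line in enumerate(fh, start=1):
                    if not line.strip():
                        continue
                    obj = json.loads(line)
                    reports.append(ImagingReport(
                        report_id=obj["report_id"],
                        patient_id=obj["patient_id"],
                        report_date=_parse_date(
                            obj["report_date"], context=f"{filename} line {lineno}"),
                        source_system=obj["source_system"],
                        modality_hint=obj.get("modality_hint"),
                        text=obj.get("text", ""),
                    ))
            tables[table] = reports
            continue
        columns = _CSV_COLUMNS[table]
        records = []
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if tuple(reader.fieldnames or ()) != columns:
                raise CohortError(
                    f"{filename}: header {reader.fieldnames} does not match expected {list(columns)}")
            for rowno, row in enumerate(reader, start=2):
                context = f"{filename} row {rowno}"
                records.append(_row_to_record(table, row, context))
        tables[table] = records
    return Cohort(**tables)
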