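"""Raw administrative record types and their CSV schemas.

Two tabular streams feed the pipeline: hospital inpatient discharge records
and outpatient service records.  Dates are calendar days (ISO 8601,
YYYY-MM-DD); the source systems carry no time of day.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path

log = logging.getLogger(__name__)

INPATIENT_COLUMNS = [
    "patient_id",
    "hospital_id",
    "admission_date",
    "discharge_date",
    "principal_dx",
    "secondary_dx",
    "procedure_code",
    "procedure_date",
    "priority",
    "resident_flag",
]
OUTPATIENT_COLUMNS = ["patient_id", "provider_id", "service_date", "tariff_code", "cost"]

#: Highest-priority elective surgery class (the cohort of interest).
PRIORITY_HIGHEST = "A"


@dataclass(frozen=True)
class InpatientRecord:
    """One hospital discharge row: diagnoses (ICD-9-CM), the surgical
    procedure with its date, the surgical priority class (``None`` when the
    priority field is missing from the record), and a residency flag that is
    False for women living outside the region or operated outside the
    regional healthcare system."""

    patient_id: str
    hospital_id: str
    admission_date: date
    discharge_date: date
    principal_dx: str
    secondary_dx: str
    procedure_code: str
    procedure_date: date | None
    priority: str | None
    resident_flag: bool

    def __post_init__(self) -> None:
        if self.admission_date > self.discharge_date:
            raise ValueError(
                f"admission_date after discharge_date for patient {self.patient_id}"
            )
        if self.procedure_date is not None and not (
            self.admission_date <= self.procedure_date <= self.discharge_date
        ):
            raise ValueError(
                f"procedure_date outside admission for patient {self.patient_id}"
            )


@dataclass(frozen=True)
class OutpatientRecord:
    """One outpatient service row: a dated tariffed service (exam or visit)."""

    patient_id: str
    provider_id: str
    service_date: date
    tariff_code: str
    cost: float

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError(f"negative cost for patient {self.patient_id}")


def _fmt_date(d: date | None) -> str:
    return d.isoformat() if d is not None else ""


def write_inpatient_csv(records: list[InpatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(INPATIENT_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.patient_id,
                    r.hospital_id,
                    _fmt_date(r.admission_date),
                    _fmt_date(r.discharge_date),
                    r.principal_dx,
                    r.secondary_dx,
                    r.procedure_code,
                    _fmt_date(r.procedure_date),
                    r.priority if r.priority is not None else "",
                    "1" if r.resident_flag else "0",
                ]
            )


def write_outpatient_csv(records: list[OutpatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(OUTPATIENT_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.patient_id,
                    r.provider_id,
                    _fmt_date(r.service_date),
                    r.tariff_code,
                    repr(r.cost) if r.cost != int(r.cost) else str(int(r.cost)),
                ]
            )


def read_inpatient_csv(path: str | Path) -> list[InpatientRecord]:
    """Parse inpatient records; malformed rows are skipped and logged with
    their (1-based, header included) line number."""
    out: list[InpatientRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    InpatientRecord(
                        patient_id=row["patient_id"],
                        hospital_id=row["hospital_id"],
                        admission_date=date.fromisoformat(row["admission_date"]),
                        discharge_date=date.fromisoformat(row["discharge_date"]),
                        principal_dx=row["principal_dx"],
                        secondary_dx=row["secondary_dx"],
                        procedure_code=row["procedure_code"],
                        procedure_date=(
                            date.fromisoformat(row["procedure_date"])
                            if row["procedure_date"]
                            else None
                        ),
                        priority=row["priority"] or None,
                        resident_flag=row["resident_flag"] in ("1", "True", "true"),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                log.warning("skipping malformed inpatient row %d: %s", lineno, exc)
    return out


def read_outpatient_csv(path: str | Path) -> list[OutpatientRecord]:
    """Parse outpatient records; malformed rows are skipped and logged with
    their line number."""
    out: list[OutpatientRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    OutpatientRecord(
                        patient_id=row["patient_id"],
                        provider_id=row["provider_id"],
                        service_date=date.fromisoformat(row["service_date"]),
                        tariff_code=row["tariff_code"],
                        cost=float(row["cost"]),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                log.warning("skipping malformed outpatient row %d: %s", lineno, exc)
    return out
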