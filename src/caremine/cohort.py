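"""Surgical cohort selection, exclusion rules, and event-log construction.

From the raw inpatient stream the builder selects women hospitalized with a
principal or secondary diagnosis of malignant breast cancer (ICD-9-CM 174.x)
or localized in-situ carcinoma (233.0 exactly) who underwent conservative
surgery (85.2x), reconstructive surgery (85.33-85.36) or mastectomy (85.4x)
as highest-priority elective surgery.  Six exclusion rules then restrict the
cohort to reliably documented single-surgery pathways, and the event log is
windowed from the date of the *last* pre-surgical biopsy (the diagnosis-date
proxy) to the date of surgery.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

from .catalog import (
    ACT_BIOPSY,
    BCT,
    BIOPSY,
    CATEGORY_LABELS,
    MAMMOGRAPHY,
    MASTECTOMY,
    RECONSTRUCTION,
    SURGERY_LABELS,
    TariffCatalog,
    ULTRASOUND,
    build_default_catalog,
)
from .eventlog import Event, EventLog, sort_events
from .records import InpatientRecord, OutpatientRecord, PRIORITY_HIGHEST
from .synthetic import EXCLUSION_RULES

#: ICD-9-CM procedure code families for the three surgery classes.
_RECONSTRUCTION_CODES = {"85.33", "85.34", "85.35", "85.36"}


def classify_surgery(procedure_code: str) -> str | None:
    """Classify an ICD-9-CM procedure code into a surgery type.

    85.2x -> breast-conserving therapy; 85.33/85.34/85.35/85.36 ->
    reconstruction; 85.4x -> mastectomy.  Returns ``None`` (no-match) for any
    other code.
    """
    code = procedure_code.strip()
    if not code:
        return None
    if code in _RECONSTRUCTION_CODES:
        return RECONSTRUCTION
    if code == "85.2" or code.startswith("85.2"):
        return BCT
    if code == "85.4" or code.startswith("85.4"):
        return MASTECTOMY
    return None


def _dx_matches(code: str) -> bool:
    """Breast-cancer diagnosis: any 174.x, or exactly 233.0."""
    code = code.strip()
    return code == "174" or code.startswith("174.") or code == "233.0"


@dataclass(frozen=True)
class SurgeryCase:
    """One qualifying surgery admission of one patient.  Biopsy dates are
    filled by the exclusion pass (they require the outpatient stream)."""

    patient_id: str
    hospital_id: str
    surgery_date: date
    surgery_type: str
    priority: str | None
    resident_flag: bool = True
    first_biopsy_date: date | None = None
    last_biopsy_date: date | None = None

    def __post_init__(self) -> None:
        if (
            self.first_biopsy_date is not None
            and self.last_biopsy_date is not None
            and self.first_biopsy_date > self.last_biopsy_date
        ):
            raise ValueError("first_biopsy_date after last_biopsy_date")
        if self.last_biopsy_date is not None and self.last_biopsy_date > self.surgery_date:
            raise ValueError("last_biopsy_date after surgery_date")


@dataclass
class ExclusionReport:
    """Per-rule exclusion counts.  Each excluded patient is attributed to the
    first rule it fails in the fixed order, so
    ``n_input = n_kept + sum(counts.values())`` always holds."""

    counts: dict[str, int] = field(default_factory=lambda: {r: 0 for r in EXCLUSION_RULES})
    n_input: int = 0
    n_kept: int = 0

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "n_kept": self.n_kept, **self.counts}


def select_cases(inpatient: list[InpatientRecord]) -> list[SurgeryCase]:
    """Emit one case per qualifying surgery admission.

    Qualifying: breast-cancer diagnosis in principal or secondary position,
    classifiable surgical procedure with a procedure date, and surgical
    priority either the highest elective class or missing (missing-priority
    patients are emitted so the exclusion pass can count them; lower-priority
    admissions are outside the cohort of interest and never emitted).
    """
    cases: list[SurgeryCase] = []
    for r in inpatient:
        if not (_dx_matches(r.principal_dx) or _dx_matches(r.secondary_dx)):
            continue
        stype = classify_surgery(r.procedure_code)
        if stype is None or r.procedure_date is None:
            continue
        if r.priority is not None and r.priority != PRIORITY_HIGHEST:
            continue
        cases.append(
            SurgeryCase(
                patient_id=r.patient_id,
                hospital_id=r.hospital_id,
                surgery_date=r.procedure_date,
                surgery_type=stype,
                priority=r.priority,
                resident_flag=r.resident_flag,
            )
        )
    return cases


def apply_exclusions(
    cases: list[SurgeryCase],
    inpatient: list[InpatientRecord],
    outpatient: list[OutpatientRecord],
    catalog: TariffCatalog | None = None,
    max_gap_days: int = 365,
) -> tuple[list[SurgeryCase], ExclusionReport]:
    """Apply the six exclusion rules, attributing each excluded patient to the
    first failing rule in the fixed order: out_of_region, multiple_surgeries,
    missing_priority, no_biopsy, no_imaging, over_365_days.

    Kept cases are returned with first/last biopsy dates filled.  The imaging
    lookback window is ``(surgery_date - 365, surgery_date]``; the last-biopsy
    window threshold is ``max_gap_days`` (gap strictly greater is excluded).
    """
    catalog = catalog or build_default_catalog()
    report = ExclusionReport()

    by_patient: dict[str, list[SurgeryCase]] = {}
    for c in cases:
        by_patient.setdefault(c.patient_id, []).append(c)
    report.n_input = len(by_patient)

    out_by_patient: dict[str, list[OutpatientRecord]] = {}
    for r in outpatient:
        out_by_patient.setdefault(r.patient_id, []).append(r)

    kept: list[SurgeryCase] = []
    for pid in sorted(by_patient):
        pcases = by_patient[pid]
        case = min(pcases, key=lambda c: c.surgery_date)
        rule = _first_failing_rule(
            pcases, case, out_by_patient.get(pid, []), catalog, max_gap_days
        )
        if rule is not None:
            report.counts[rule] += 1
            continue
        biopsy_dates = sorted(
            r.service_date
            for r in out_by_patient.get(pid, [])
            if catalog.category_of(r.tariff_code) == BIOPSY
            and r.service_date <= case.surgery_date
        )
        kept.append(
            replace(
                case,
                first_biopsy_date=biopsy_dates[0],
                last_biopsy_date=biopsy_dates[-1],
            )
        )
    report.n_kept = len(kept)
    assert report.n_input == report.n_kept + report.n_excluded
    return kept, report


def _first_failing_rule(
    pcases: list[SurgeryCase],
    case: SurgeryCase,
    outrows: list[OutpatientRecord],
    catalog: TariffCatalog,
    max_gap_days: int,
) -> str | None:
    if any(not c.resident_flag for c in pcases):
        return "out_of_region"
    if len(pcases) > 1:
        return "multiple_surgeries"
    if case.priority is None:
        return "missing_priority"
    biopsy_dates = [
        r.service_date
        for r in outrows
        if catalog.category_of(r.tariff_code) == BIOPSY
        and r.service_date <= case.surgery_date
    ]
    if not biopsy_dates:
        return "no_biopsy"
    window_start = case.surgery_date - timedelta(days=365)
    has_imaging = any(
        catalog.category_of(r.tariff_code) in (MAMMOGRAPHY, ULTRASOUND)
        and window_start < r.service_date <= case.surgery_date
        for r in outrows
    )
    if not has_imaging:
        return "no_imaging"
    if (case.surgery_date - max(biopsy_dates)).days > max_gap_days:
        return "over_365_days"
    return None


def build_event_log(
    cases: list[SurgeryCase],
    outpatient: list[OutpatientRecord],
    catalog: TariffCatalog | None = None,
) -> EventLog:
    """Window each kept case from its last biopsy to its surgery.

    The trace contains the whitelisted outpatient activities dated within
    ``[last_biopsy_date, surgery_date]`` plus the surgery event; activities
    outside the whitelist (pre-surgery workup, follow-up exams) are dropped.
    By construction the trace starts with exactly one biopsy (same-day
    duplicate biopsy rows collapse to the lowest tariff code) and ends with
    exactly one surgery.  All events carry the surgery hospital as grouping
    key.
    """
    catalog = catalog or build_default_catalog()
    out_by_patient: dict[str, list[OutpatientRecord]] = {}
    for r in outpatient:
        out_by_patient.setdefault(r.patient_id, []).append(r)

    log = EventLog()
    for case in sorted(cases, key=lambda c: c.patient_id):
        if case.last_biopsy_date is None:
            raise ValueError(
                f"case {case.patient_id} lacks biopsy dates; run apply_exclusions first"
            )
        events: list[Event] = []
        seen_biopsy = False
        for r in sorted(
            out_by_patient.get(case.patient_id, []),
            key=lambda r: (r.service_date, r.tariff_code),
        ):
            cat = catalog.category_of(r.tariff_code)
            if cat is None:
                continue  # outside the 7-activity whitelist
            if not case.last_biopsy_date <= r.service_date <= case.surgery_date:
                continue
            if cat == BIOPSY:
                if seen_biopsy:
                    continue  # collapse same-day duplicate biopsy rows
                seen_biopsy = True
            events.append(
                Event(
                    case_id=case.patient_id,
                    activity=CATEGORY_LABELS[cat],
                    date=r.service_date,
                    hospital_id=case.hospital_id,
                    tariff_code=r.tariff_code,
                    cost=r.cost,
                )
            )
        events.append(
            Event(
                case_id=case.patient_id,
                activity=SURGERY_LABELS[case.surgery_type],
                date=case.surgery_date,
                hospital_id=case.hospital_id,
            )
        )
        events = sort_events(events)
        assert events[0].activity == ACT_BIOPSY and events[-1].activity in SURGERY_LABELS.values(), (
            f"trace of {case.patient_id} violates the windowing guarantee"
        )
        log.traces[case.patient_id] = events
    return log


CASE_COLUMNS = [
    "patient_id",
    "hospital_id",
    "surgery_date",
    "surgery_type",
    "priority",
    "first_biopsy_date",
    "last_biopsy_date",
]


def write_cases_csv(cases: list[SurgeryCase], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CASE_COLUMNS)
        for c in sorted(cases, key=lambda c: c.patient_id):
            w.writerow(
                [
                    c.patient_id,
                    c.hospital_id,
                    c.surgery_date.isoformat(),
                    c.surgery_type,
                    c.priority or "",
                    c.first_biopsy_date.isoformat() if c.first_biopsy_date else "",
                    c.last_biopsy_date.isoformat() if c.last_biopsy_date else "",
                ]
            )


def read_cases_csv(path: str | Path) -> list[SurgeryCase]:
    cases: list[SurgeryCase] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            cases.append(
                SurgeryCase(
                    patient_id=row["patient_id"],
                    hospital_id=row["hospital_id"],
                    surgery_date=date.fromisoformat(row["surgery_date"]),
                    surgery_type=row["surgery_type"],
                    priority=row["priority"] or None,
                    first_biopsy_date=(
                        date.fromisoformat(row["first_biopsy_date"])
                        if row["first_biopsy_date"]
                        else None
                    ),
                    last_biopsy_date=(
                        date.fromisoformat(row["last_biopsy_date"])
                        if row["last_biopsy_date"]
                        else None
                    ),
                )
            )
    return cases
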