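"""Per-hospital cohort summaries, case-duration distributions, and 30-day
surgical-guideline adherence.

Two duration definitions coexist and are never silently mixed: the
table-style case duration runs from the *first* biopsy to surgery, while the
guideline adherence statistic uses the *last* biopsy (the diagnosis-date
proxy) because the 30-day target counts from the end of the diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import SurgeryCase
from .eventlog import EventLog

MODES = ("from_first_biopsy", "from_last_biopsy")


@dataclass
class DurationDistribution:
    """Biopsy-to-surgery durations (days) of one hospital's cases."""

    hospital_id: str
    mode: str
    values: list[int]

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def iqr(self) -> tuple[float, float]:
        # linear interpolation between order statistics
        lo, hi = np.percentile(self.values, [25, 75])
        return float(lo), float(hi)


@dataclass
class HospitalSummary:
    hospital_id: str
    n_patients: int
    n_events: int
    avg_events_per_patient: float  # 1 decimal
    median_case_duration_days: float
    share_of_total_cases: float  # percent


def _duration(case: SurgeryCase, mode: str) -> int:
    if mode == "from_first_biopsy":
        start = case.first_biopsy_date
    elif mode == "from_last_biopsy":
        start = case.last_biopsy_date
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if start is None:
        raise ValueError(f"case {case.patient_id} lacks biopsy dates")
    return (case.surgery_date - start).days


def case_durations(
    cases: list[SurgeryCase], mode: str = "from_first_biopsy"
) -> dict[str, DurationDistribution]:
    """Per-hospital duration distribution under the chosen definition."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    grouped: dict[str, list[int]] = {}
    for c in cases:
        grouped.setdefault(c.hospital_id, []).append(_duration(c, mode))
    return {
        h: DurationDistribution(h, mode, sorted(v)) for h, v in sorted(grouped.items())
    }


def hospital_summary(log: EventLog, cases: list[SurgeryCase]) -> list[HospitalSummary]:
    """Table of per-hospital volume, event intensity, median case duration
    (first-biopsy definition) and share of total cases."""
    by_hosp: dict[str, list[SurgeryCase]] = {}
    for c in cases:
        by_hosp.setdefault(c.hospital_id, []).append(c)
    events_by_hosp: dict[str, int] = {}
    for trace in log.traces.values():
        h = trace[0].hospital_id
        events_by_hosp[h] = events_by_hosp.get(h, 0) + len(trace)
    total = len(cases)
    durations = case_durations(cases, "from_first_biopsy")
    out = []
    for h in sorted(by_hosp):
        n = len(by_hosp[h])
        n_ev = events_by_hosp.get(h, 0)
        out.append(
            HospitalSummary(
                hospital_id=h,
                n_patients=n,
                n_events=n_ev,
                avg_events_per_patient=round(n_ev / n, 1),
                median_case_duration_days=durations[h].median,
                share_of_total_cases=100.0 * n / total,
            )
        )
    return out


def adherence_30d(
    cases: list[SurgeryCase], threshold_days: int = 30
) -> dict[str, float]:
    """Per-hospital fraction of cases whose last-biopsy-to-surgery interval is
    at most ``threshold_days`` (the guideline's 30-day target; closed
    threshold)."""
    grouped: dict[str, list[int]] = {}
    for c in cases:
        grouped.setdefault(c.hospital_id, []).append(_duration(c, "from_last_biopsy"))
    return {
        h: sum(d <= threshold_days for d in v) / len(v)
        for h, v in sorted(grouped.items())
    }
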