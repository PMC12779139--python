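"""Small hand-written example logs used in documentation and checks."""

from __future__ import annotations

from datetime import date, timedelta

from .catalog import (
    ACT_BCT,
    ACT_BIOPSY,
    ACT_MAMMOGRAPHY,
    ACT_MASTECTOMY,
    ACT_ULTRASOUND,
    ACT_VISIT,
)
from .eventlog import Event, EventLog


def two_patient_example_log() -> EventLog:
    """The two hypothetical patients of the worked example.

    Both cases start with a biopsy.  Patient 1 proceeds *directly* from the
    biopsy to an outpatient visit after 55 days — the longest elapsed time
    between any two activities — is then examined by a specialist
    (mammography) and sent to surgery.  Patient 2 takes a different, more
    complex route through imaging before surgery, so only one of the two
    cases contains the direct biopsy-to-visit transition: its case coverage
    is 50% and its median waiting time 55 days.
    """
    t0 = date(2018, 1, 5)

    def d(days: int) -> date:
        return t0 + timedelta(days=days)

    h = "HOSP-A"
    traces = {
        "patient-1": [
            Event("patient-1", ACT_BIOPSY, d(0), h),
            Event("patient-1", ACT_VISIT, d(55), h),
            Event("patient-1", ACT_MAMMOGRAPHY, d(65), h),
            Event("patient-1", ACT_BCT, d(80), h),
        ],
        "patient-2": [
            Event("patient-2", ACT_BIOPSY, d(0), h),
            Event("patient-2", ACT_MAMMOGRAPHY, d(12), h),
            Event("patient-2", ACT_ULTRASOUND, d(12), h),
            Event("patient-2", ACT_VISIT, d(32), h),
            Event("patient-2", ACT_MASTECTOMY, d(62), h),
        ],
    }
    return EventLog(traces=traces)
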