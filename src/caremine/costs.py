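"""Per-hospital, per-category diagnostic cost and variation tables.

For each surgery hospital and each exam category (biopsy, ultrasound,
mammography, visit) the summary reports the median, mean, and sample
standard deviation of the per-patient cost distribution — *including*
patients with zero services of the category, so that
``mean_cost * n_patients`` equals the total observed spend — together with
the frequency (exams per treated patient) and the number of distinct tariff
variants observed.  The mean total cost per patient combines the four
categories and algebraically equals the grand spend divided by the number of
patients.

Costs are in scaled standardized euros (s€); the scaling factor is a plain
multiplier (default 1) recorded in the summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import (
    CATEGORIES,
    CATEGORY_LABELS,
    TariffCatalog,
    build_default_catalog,
)
from .eventlog import Event, EventLog

_LABEL_TO_CATEGORY = {v: k for k, v in CATEGORY_LABELS.items()}


@dataclass
class CategoryCostStats:
    """Cost/volume summary of one exam category at one hospital."""

    median_cost: float
    mean_cost: float
    sd_cost: float
    frequency: float  # exams per patient
    types: int  # distinct tariff codes observed


@dataclass
class CostSummary:
    """Per-category cost stats plus the mean total diagnostic cost per
    patient for one hospital."""

    hospital_id: str
    n_patients: int
    categories: dict[str, CategoryCostStats] = field(default_factory=dict)
    scale: float = 1.0

    @property
    def mean_total_cost(self) -> float:
        return sum(s.mean_cost for s in self.categories.values())


def per_patient_cost(trace: list[Event], category: str) -> float:
    """Total cost of a case's in-window services of one category (0 if none).

    Events carry their category through the activity label, so no catalog is
    needed here.
    """
    label = CATEGORY_LABELS[category]
    return sum(e.cost or 0.0 for e in trace if e.activity == label)


def cost_summary(
    log: EventLog,
    catalog: TariffCatalog | None = None,
    scale: float = 1.0,
) -> dict[str, CostSummary]:
    """Per-hospital cost and variation tables over the windowed event log.

    The per-patient cost distributions include zero-cost patients; the SD is
    the sample (n-1) standard deviation (0 for fewer than two patients).
    ``scale`` multiplies all cost outputs (s€ standardization factor).
    """
    catalog = catalog or build_default_catalog()
    summaries: dict[str, CostSummary] = {}
    for hosp, sublog in sorted(log.by_hospital().items()):
        n = sublog.n_cases
        if n == 0:  # pragma: no cover - by_hospital never yields empty sublogs
            continue
        summary = CostSummary(hospital_id=hosp, n_patients=n, scale=scale)
        for category in CATEGORIES:
            label = CATEGORY_LABELS[category]
            costs = []
            n_events = 0
            codes: set[str] = set()
            for trace in sublog.traces.values():
                costs.append(scale * per_patient_cost(trace, category))
                for e in trace:
                    if e.activity == label:
                        n_events += 1
                        if e.tariff_code:
                            codes.add(e.tariff_code)
            arr = np.asarray(costs, dtype=float)
            summary.categories[category] = CategoryCostStats(
                median_cost=float(np.median(arr)),
                mean_cost=float(arr.mean()),
                sd_cost=float(arr.std(ddof=1)) if n > 1 else 0.0,
                frequency=n_events / n,
                types=len(codes),
            )
        summaries[hosp] = summary
    return summaries


def mean_total_cost(summary: CostSummary) -> float:
    """Mean total diagnostic cost per patient: the sum over categories of the
    mean per-patient cost (equivalently, sum of mean cost per exam times
    frequency)."""
    return summary.mean_total_cost
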