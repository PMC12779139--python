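"""Event-log container (cases, traces, events) and its CSV / XES exchange formats.

A *case* is one patient; its *trace* is the chronologically ordered sequence
of whitelisted activities from the last pre-surgical biopsy to the surgery,
at day granularity.  Cases carry the hospital where the surgery took place as
grouping key.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

from .catalog import ACTIVITY_WHITELIST, DAY_ORDER


@dataclass(frozen=True)
class Event:
    """One dated activity of a case.  ``hospital_id`` is the surgery hospital
    of the case (the analysis groups all of a patient's events by it);
    tariff code and cost are present for outpatient services only."""

    case_id: str
    activity: str
    date: date
    hospital_id: str
    tariff_code: str | None = None
    cost: float | None = None

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITY_WHITELIST:
            raise ValueError(f"activity {self.activity!r} outside the whitelist")


@dataclass
class EventLog:
    """Traces keyed by case id, each a chronologically ordered event list."""

    traces: dict[str, list[Event]] = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return len(self.traces)

    @property
    def n_events(self) -> int:
        return sum(len(t) for t in self.traces.values())

    def hospital_of(self, case_id: str) -> str:
        return self.traces[case_id][0].hospital_id

    def hospitals(self) -> list[str]:
        return sorted({t[0].hospital_id for t in self.traces.values() if t})

    def by_hospital(self) -> dict[str, "EventLog"]:
        """Split into per-hospital sublogs (by surgery hospital)."""
        out: dict[str, EventLog] = {}
        for cid, trace in self.traces.items():
            out.setdefault(trace[0].hospital_id, EventLog()).traces[cid] = trace
        return out

    def relabel_hospitals(self, mapping: dict[str, str]) -> "EventLog":
        from dataclasses import replace

        return EventLog(
            traces={
                cid: [replace(e, hospital_id=mapping.get(e.hospital_id, e.hospital_id)) for e in t]
                for cid, t in self.traces.items()
            }
        )


def sort_events(events: list[Event]) -> list[Event]:
    """Chronological order with the canonical within-day tie-break
    (biopsy < mammography < ultrasound < visit < surgery, then tariff code)."""
    return sorted(
        events, key=lambda e: (e.date, DAY_ORDER[e.activity], e.tariff_code or "")
    )


LOG_COLUMNS = ["case_id", "activity", "date", "hospital_id", "tariff_code", "cost"]


def write_log_csv(log: EventLog, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(LOG_COLUMNS)
        for cid in sorted(log.traces):
            for e in log.traces[cid]:
                w.writerow(
                    [
                        e.case_id,
                        e.activity,
                        e.date.isoformat(),
                        e.hospital_id,
                        e.tariff_code or "",
                        "" if e.cost is None else repr(e.cost),
                    ]
                )


def read_log_csv(path: str | Path) -> EventLog:
    """Read an event-log CSV; malformed rows raise with their line number."""
    log = EventLog()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                ev = Event(
                    case_id=row["case_id"],
                    activity=row["activity"],
                    date=date.fromisoformat(row["date"]),
                    hospital_id=row["hospital_id"],
                    tariff_code=row["tariff_code"] or None,
                    cost=float(row["cost"]) if row["cost"] else None,
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"malformed event-log row at line {lineno}: {exc}") from exc
            log.traces.setdefault(ev.case_id, []).append(ev)
    return log


def export_xes(log: EventLog, path: str | Path) -> None:
    """Write the log in the XES interchange format.

    Case id becomes the trace's ``concept:name``, the activity label the
    event's ``concept:name``, and the day the ``time:timestamp`` at midnight
    UTC (the source records carry no time of day).
    """
    root = ET.Element("log", {"xes.version": "1.0", "xes.features": "nested-attributes"})
    ET.SubElement(
        root,
        "extension",
        {"name": "Concept", "prefix": "concept", "uri": "http://www.xes-standard.org/concept.xesext"},
    )
    ET.SubElement(
        root,
        "extension",
        {"name": "Time", "prefix": "time", "uri": "http://www.xes-standard.org/time.xesext"},
    )
    for cid in sorted(log.traces):
        trace_el = ET.SubElement(root, "trace")
        ET.SubElement(trace_el, "string", {"key": "concept:name", "value": cid})
        ET.SubElement(
            trace_el, "string", {"key": "hospital", "value": log.hospital_of(cid)}
        )
        for e in log.traces[cid]:
            ev_el = ET.SubElement(trace_el, "event")
            ET.SubElement(ev_el, "string", {"key": "concept:name", "value": e.activity})
            ET.SubElement(
                ev_el,
                "date",
                {"key": "time:timestamp", "value": f"{e.date.isoformat()}T00:00:00+00:00"},
            )
            if e.tariff_code is not None:
                ET.SubElement(ev_el, "string", {"key": "tariff_code", "value": e.tariff_code})
            if e.cost is not None:
                ET.SubElement(ev_el, "float", {"key": "cost", "value": repr(e.cost)})
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="utf-8")
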