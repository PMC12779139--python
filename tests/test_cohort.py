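"""Cohort selection, the six exclusion rules, and event-log construction."""

import xml.etree.ElementTree as ET
from datetime import date, timedelta

import pytest

import caremine as cm
from caremine.catalog import BCT, MASTECTOMY, RECONSTRUCTION
from caremine.cohort import (
    SurgeryCase,
    apply_exclusions,
    build_event_log,
    classify_surgery,
    read_cases_csv,
    select_cases,
    write_cases_csv,
)
from caremine.eventlog import export_xes, read_log_csv, write_log_csv
from caremine.records import InpatientRecord, OutpatientRecord


def inpatient_row(
    pid="P1",
    dx="174.9",
    proc="85.21",
    surgery=date(2018, 6, 1),
    priority="A",
    resident=True,
    hospital="H",
):
    return InpatientRecord(
        patient_id=pid,
        hospital_id=hospital,
        admission_date=surgery,
        discharge_date=surgery + timedelta(days=3),
        principal_dx=dx,
        secondary_dx="",
        procedure_code=proc,
        procedure_date=surgery,
        priority=priority,
        resident_flag=resident,
    )


def service(pid, code, day, cost=1.0):
    return OutpatientRecord(pid, "H", day, code, cost)


BIOPSY_CODE = "91.39.4"
MAMMO_CODE = "87.37.1"
US_CODE = "88.73.1"
VISIT_CODE = "89.7A.3"


class TestClassifySurgery:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("85.21", BCT),
            ("85.23", BCT),
            ("85.2", BCT),
            ("85.33", RECONSTRUCTION),
            ("85.34", RECONSTRUCTION),
            ("85.35", RECONSTRUCTION),
            ("85.36", RECONSTRUCTION),
            ("85.41", MASTECTOMY),
            ("85.48", MASTECTOMY),
            ("85.50", None),
            ("86.21", None),
            ("", None),
        ],
    )
    def test_code_families(self, code, expected):
        assert classify_surgery(code) == expected


class TestSelectCases:
    def test_in_situ_diagnosis_with_conservative_surgery(self):
        cases = select_cases([inpatient_row(dx="233.0", proc="85.21")])
        assert len(cases) == 1 and cases[0].surgery_type == BCT

    def test_secondary_diagnosis_qualifies(self):
        rec = inpatient_row(dx="401.9")
        rec = InpatientRecord(**{**rec.__dict__, "secondary_dx": "174.2"})
        assert len(select_cases([rec])) == 1

    def test_non_breast_diagnosis_rejected(self):
        assert select_cases([inpatient_row(dx="153.4")]) == []

    def test_in_situ_requires_exact_code(self):
        assert select_cases([inpatient_row(dx="233.1")]) == []

    def test_lower_priority_not_emitted(self):
        assert select_cases([inpatient_row(priority="B")]) == []

    def test_missing_priority_emitted_for_exclusion_counting(self):
        cases = select_cases([inpatient_row(priority=None)])
        assert len(cases) == 1 and cases[0].priority is None

    def test_count_matches_independent_scan(self, demo_config):
        inp, _ = cm.generate_cohort(demo_config)
        # brute-force re-scan with independently written predicates
        def dx_ok(c):
            return c.startswith("174") or c == "233.0"

        def proc_ok(c):
            return (
                c.startswith("85.2")
                or c in ("85.33", "85.34", "85.35", "85.36")
                or c.startswith("85.4")
            )

        expected = sum(
            1
            for r in inp
            if (dx_ok(r.principal_dx) or dx_ok(r.secondary_dx))
            and proc_ok(r.procedure_code)
            and r.priority in (None, "A")
        )
        assert len(select_cases(inp)) == expected


def clean_patient(pid="P1", surgery=date(2018, 6, 1)):
    inp = [inpatient_row(pid=pid, surgery=surgery)]
    outp = [
        service(pid, BIOPSY_CODE, surgery - timedelta(days=40)),
        service(pid, MAMMO_CODE, surgery - timedelta(days=50)),
    ]
    return inp, outp


class TestApplyExclusions:
    def test_clean_case_kept(self, catalog):
        inp, outp = clean_patient()
        kept, report = apply_exclusions(select_cases(inp), inp, outp, catalog)
        assert len(kept) == 1
        assert all(v == 0 for v in report.counts.values())
        assert kept[0].last_biopsy_date == date(2018, 6, 1) - timedelta(days=40)

    def test_gap_366_days_excluded_as_outlier(self, catalog):
        surgery = date(2018, 12, 1)
        inp = [inpatient_row(surgery=surgery)]
        outp = [
            service("P1", BIOPSY_CODE, surgery - timedelta(days=366)),
            service("P1", MAMMO_CODE, surgery - timedelta(days=100)),
        ]
        _, report = apply_exclusions(select_cases(inp), inp, outp, catalog)
        assert report.counts["over_365_days"] == 1

    def test_gap_365_days_kept(self, catalog):
        surgery = date(2018, 12, 1)
        inp = [inpatient_row(surgery=surgery)]
        outp = [
            service("P1", BIOPSY_CODE, surgery - timedelta(days=365)),
            service("P1", MAMMO_CODE, surgery - timedelta(days=100)),
        ]
        kept, _ = apply_exclusions(select_cases(inp), inp, outp, catalog)
        assert len(kept) == 1

    def test_two_surgeries_excluded(self, catalog):
        inp = [
            inpatient_row(surgery=date(2018, 6, 1)),
            inpatient_row(surgery=date(2018, 8, 1)),
        ]
        _, outp = clean_patient()
        _, report = apply_exclusions(select_cases(inp), inp, outp, catalog)
        assert report.counts["multiple_surgeries"] == 1

    def test_non_resident_excluded_before_other_rules(self, catalog):
        inp = [inpatient_row(resident=False, priority=None)]
        _, report = apply_exclusions(select_cases(inp), inp, [], catalog)
        assert report.counts["out_of_region"] == 1
        assert report.counts["missing_priority"] == 0

    def test_no_biopsy_precedes_no_imaging(self, catalog):
        inp = [inpatient_row()]
        _, report = apply_exclusions(select_cases(inp), inp, [], catalog)
        assert report.counts["no_biopsy"] == 1
        assert report.counts["no_imaging"] == 0

    def test_imaging_older_than_a_year_does_not_count(self, catalog):
        surgery = date(2018, 12, 1)
        inp = [inpatient_row(surgery=surgery)]
        outp = [
            service("P1", BIOPSY_CODE, surgery - timedelta(days=40)),
            service("P1", US_CODE, surgery - timedelta(days=366)),
        ]
        _, report = apply_exclusions(select_cases(inp), inp, outp, catalog)
        assert report.counts["no_imaging"] == 1

    def test_conservation_invariant(self, demo_config):
        inp, outp = cm.generate_cohort(demo_config)
        _, report = apply_exclusions(
            select_cases(inp), inp, outp, demo_config.catalog
        )
        assert report.n_input == report.n_kept + report.n_excluded

    def test_idempotence_on_kept_cases(self, demo_config):
        inp, outp = cm.generate_cohort(demo_config)
        kept, _ = apply_exclusions(select_cases(inp), inp, outp, demo_config.catalog)
        kept2, report2 = apply_exclusions(kept, inp, outp, demo_config.catalog)
        assert report2.n_excluded == 0
        assert kept2 == kept

    def test_relaxing_threshold_never_decreases_kept(self, demo_config):
        inp, outp = cm.generate_cohort(demo_config)
        cases = select_cases(inp)
        kept_counts = [
            apply_exclusions(cases, inp, outp, demo_config.catalog, max_gap_days=t)[1].n_kept
            for t in (200, 365, 500, 10_000)
        ]
        assert kept_counts == sorted(kept_counts)


class TestBuildEventLog:
    def test_window_starts_at_last_biopsy(self, catalog):
        surgery = date(2018, 3, 2)  # day 60
        t0 = date(2018, 1, 1)
        inp = [inpatient_row(surgery=surgery)]
        outp = [
            service("P1", BIOPSY_CODE, t0),
            service("P1", BIOPSY_CODE, t0 + timedelta(days=20)),
            service("P1", MAMMO_CODE, t0 + timedelta(days=10)),
            service("P1", VISIT_CODE, t0 + timedelta(days=40)),
        ]
        kept, _ = apply_exclusions(select_cases(inp), inp, outp, catalog)
        log = build_event_log(kept, outp, catalog)
        acts = [(e.activity, e.date) for e in log.traces["P1"]]
        assert acts == [
            ("Biopsy", t0 + timedelta(days=20)),
            ("Outpatient visit", t0 + timedelta(days=40)),
            ("BCT", surgery),
        ]

    def test_minimal_two_event_trace(self, catalog):
        surgery = date(2018, 6, 1)
        inp = [inpatient_row(surgery=surgery)]
        outp = [
            service("P1", BIOPSY_CODE, surgery - timedelta(days=30)),
            service("P1", MAMMO_CODE, surgery - timedelta(days=45)),
        ]
        kept, _ = apply_exclusions(select_cases(inp), inp, outp, catalog)
        log = build_event_log(kept, outp, catalog)
        assert [e.activity for e in log.traces["P1"]] == ["Biopsy", "BCT"]

    def test_unknown_tariff_codes_dropped(self, catalog):
        surgery = date(2018, 6, 1)
        inp = [inpatient_row(surgery=surgery)]
        outp = [
            service("P1", BIOPSY_CODE, surgery - timedelta(days=30)),
            service("P1", MAMMO_CODE, surgery - timedelta(days=20)),
            service("P1", "89.52", surgery - timedelta(days=10)),  # electrocardiogram
        ]
        kept, _ = apply_exclusions(select_cases(inp), inp, outp, catalog)
        log = build_event_log(kept, outp, catalog)
        assert [e.activity for e in log.traces["P1"]] == ["Biopsy", "Mammography", "BCT"]

    def test_windowing_guarantee_on_synthetic_cohort(self, demo_config):
        inp, outp = cm.generate_cohort(demo_config)
        kept, _ = apply_exclusions(select_cases(inp), inp, outp, demo_config.catalog)
        log = build_event_log(kept, outp, demo_config.catalog)
        surgeries = {"BCT", "Mastectomy", "Reconstruction"}
        for trace in log.traces.values():
            assert trace[0].activity == "Biopsy"
            assert trace[-1].activity in surgeries
            assert sum(e.activity == "Biopsy" for e in trace) == 1
            assert sum(e.activity in surgeries for e in trace) == 1
            dates = [e.date for e in trace]
            assert dates == sorted(dates)

    def test_event_count_matches_brute_force(self, demo_config):
        inp, outp = cm.generate_cohort(demo_config)
        kept, _ = apply_exclusions(select_cases(inp), inp, outp, demo_config.catalog)
        log = build_event_log(kept, outp, demo_config.catalog)
        catalog = demo_config.catalog
        expected = 0
        for c in kept:
            rows = [
                r
                for r in outp
                if r.patient_id == c.patient_id
                and c.last_biopsy_date <= r.service_date <= c.surgery_date
                and catalog.category_of(r.tariff_code) is not None
            ]
            expected += len(rows) + 1  # plus the surgery event
        assert log.n_events == expected

    def test_missing_biopsy_dates_rejected(self, catalog):
        case = SurgeryCase("P1", "H", date(2018, 6, 1), BCT, "A")
        with pytest.raises(ValueError, match="biopsy dates"):
            build_event_log([case], [], catalog)


class TestLogIO:
    def _small_log(self, catalog, demo_config):
        inp, outp = cm.generate_cohort(demo_config)
        kept, _ = apply_exclusions(select_cases(inp), inp, outp, demo_config.catalog)
        return build_event_log(kept[:3] if len(kept) > 3 else kept, outp, catalog)

    def test_csv_round_trip(self, tmp_path, catalog, demo_config):
        log = self._small_log(catalog, demo_config)
        write_log_csv(log, tmp_path / "log.csv")
        assert read_log_csv(tmp_path / "log.csv") == log

    def test_empty_log_round_trip(self, tmp_path):
        from caremine.eventlog import EventLog

        write_log_csv(EventLog(), tmp_path / "log.csv")
        assert read_log_csv(tmp_path / "log.csv").traces == {}

    def test_xes_structure(self, tmp_path, catalog, demo_config):
        log = self._small_log(catalog, demo_config)
        export_xes(log, tmp_path / "log.xes")
        root = ET.parse(tmp_path / "log.xes").getroot()
        traces = root.findall("trace")
        assert len(traces) == log.n_cases
        first = traces[0]
        cid = first.find("string[@key='concept:name']").attrib["value"]
        events = first.findall("event")
        assert len(events) == len(log.traces[cid])
        stamp = events[0].find("date[@key='time:timestamp']").attrib["value"]
        assert stamp.endswith("T00:00:00+00:00")

    def test_cases_csv_round_trip(self, tmp_path, demo_config):
        inp, outp = cm.generate_cohort(demo_config)
        kept, _ = apply_exclusions(select_cases(inp), inp, outp, demo_config.catalog)
        write_cases_csv(kept, tmp_path / "cases.csv")
        assert read_cases_csv(tmp_path / "cases.csv") == sorted(
            kept, key=lambda c: c.patient_id
        )
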