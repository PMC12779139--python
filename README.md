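# caremine

Process mining of breast-cancer care pathways from administrative hospital
records.

Regional healthcare systems record every reimbursed service — inpatient
discharges with ICD-9-CM diagnosis and procedure codes, outpatient exams with
tariff codes — but those records say little, by themselves, about how patients
actually move through a care pathway. `caremine` turns the two raw record
streams into *event logs* (one trace of dated activities per patient) for the
diagnostic segment of the breast-cancer surgical pathway, from the last
pre-surgical biopsy to surgery, and mines them into annotated process maps and
per-hospital performance and cost tables. It is aimed at health-services
researchers and hospital quality teams who want to compare real-world practice
across providers against a recommended pathway (e.g. the 30-day
diagnosis-to-surgery target for highest-priority elective surgery).

## What it computes

**Cohort construction.** Women hospitalized with a principal or secondary
diagnosis of malignant breast cancer (174.x) or in-situ carcinoma (233.0) who
underwent conservative surgery (85.2x), reconstruction (85.33–85.36) or
mastectomy (85.4x) as highest-priority elective surgery. Six exclusion rules
(applied in a fixed order, each patient attributed to the first failing rule)
restrict the cohort to reliably documented single-surgery pathways:
out-of-region care, multiple surgeries, missing surgical priority, no biopsy
before surgery, no mammography/ultrasound within one year before surgery, and
a last-biopsy-to-surgery interval above 365 days.

**Directly-follows process maps.** The mined map has an arrow A → B iff at
least one patient performs B immediately after A. Each edge carries its
occurrence count, *case coverage* (fraction of patients taking the transition
at least once) and the multiset of day gaps, supporting a frequency view, a
performance view (median by default — robust to the long upper tails of
waiting times) and a mixed view with secondary labels, rendered as DOT.
Same-day transitions are labeled *instant*; dashed arrows mark where cases
start and end. An *importance zoom* keeps the top fraction of activities and
paths while guaranteeing that no displayed activity is disconnected from the
start or end of the process.

**Performance and cost tables.** Per hospital: patient/event volumes, case
duration distributions (from first biopsy, as in volume tables, or from last
biopsy, the diagnosis proxy used for the 30-day adherence statistic), and
per-exam-category cost tables (median / mean / sample SD of per-patient cost,
frequency = exams per patient, number of tariff variants), plus the mean total
diagnostic cost per patient and cross-hospital comparison tables.

**Synthetic data.** Because real administrative data are confidential, a
seeded generator produces record streams with the structure the analysis
assumes — hospitals of heterogeneous volume, four biopsy tariff variants with
right-skewed costs, log-normal transition waiting times, same-day exam
clusters, visit loops, and controlled injection of violations of each
exclusion rule — so the whole pipeline is testable offline.

## Worked example

The package ships a two-patient example log in which only the first patient
moves directly from biopsy to an outpatient visit, after 55 days:

```python
from caremine import two_patient_example_log, mine_map, edge_statistic

pmap = mine_map(two_patient_example_log())
edge = ("Biopsy", "Outpatient visit")
print(pmap.edge_coverage_pct(edge))        # 50.0  -> half the cases take it
print(edge_statistic(pmap, edge, "median"))  # 55.0 -> median waiting, days
```

The full pipeline runs from the command line. With the built-in four-hospital
demo conditions:

```sh
caremine run-all --seed 42 --out demo/
# wrote 37 artifacts to demo/
```

`demo/` then contains the raw record CSVs, the exclusion report, per-hospital
event logs (CSV and XES), process maps (JSON plus frequency / performance /
mixed DOT views at the default 80% path zoom), summary tables and the
cross-hospital comparison tables, with hospitals anonymized H1…H4 by volume.
The exclusion report for seed 42 reads:

```json
{"n_input": 300, "n_kept": 273, "out_of_region": 5, "multiple_surgeries": 2,
 "missing_priority": 4, "no_biopsy": 2, "no_imaging": 9, "over_365_days": 5}
```

i.e. 273 of 300 generated patients survive the six rules, and the per-rule
counts always sum to the number excluded. The head of the cost table
(`demo/cost_summary.csv`, costs in scaled euros per patient):

```
hospital,category,Median,Mean,S.D.,Frequency,Types
H1,biopsy,2.20,9.65,15.02,1.00,4
H1,mammography,1.78,2.19,1.60,0.95,3
H1,ultrasound,0.00,0.99,1.28,0.59,2
H1,visit,5.43,9.18,8.42,1.16,2
```

Biopsy frequency is exactly 1.00 by construction — the event window starts at
each patient's last biopsy — while the mean biopsy cost far exceeds the
median because a few expensive stereotactic variants coexist with cheap
fine-needle ones.

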