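# Methods

This note records the models, parameter choices and numerical conventions
behind `caremine`, and what the synthetic study conditions do and do not show
about real administrative data.

## Pathway segment and event model

The analysis covers the diagnostic segment of the breast-cancer surgical
pathway. Administrative records carry day granularity only, so an *event* is
an (activity, calendar day) pair; there are no start/end times. The activity
vocabulary is a fixed seven-label whitelist: Biopsy, Mammography, Ultrasound,
Outpatient visit, and the three surgery classes (BCT, Mastectomy,
Reconstruction). Outpatient services outside these categories (pre-surgical
workup such as electrocardiography, post-surgical follow-up) are dropped when
the log is built.

Because the exact diagnosis date is not recorded, the **last biopsy before
surgery** serves as the diagnosis proxy and as the start of each trace; the
surgery date is the end. A consequence worth stating explicitly: every
windowed trace contains exactly one biopsy (the window starts at the last
one) and exactly one surgery, so the per-patient biopsy frequency in the cost
tables is exactly 1 on any filtered cohort. Case-duration tables use the
**first** biopsy instead, matching the usual volume-table convention; the two
definitions are exposed as explicit modes (`from_first_biopsy`,
`from_last_biopsy`) and never mixed silently.

Within-day ties are broken by a canonical order — biopsy < mammography <
ultrasound < visit < surgery, then tariff code. The records justify no finer
ordering; fixing one makes every downstream artifact deterministic.

## Cohort rules

Selection: principal or secondary diagnosis in the 174.x family (prefix
match) or exactly 233.0; procedure classified by code family (85.2x
conservative; 85.33–85.36 reconstruction, exact; 85.4x mastectomy);
highest-priority elective admissions only. Records with a *missing* priority
field are selected and then counted by the exclusion pass, since "no priority
recorded" is itself an exclusion rule; lower-priority admissions are simply
outside the cohort of interest.

The six exclusion rules are evaluated in a fixed order — out_of_region,
multiple_surgeries, missing_priority, no_biopsy, no_imaging, over_365_days —
and each excluded patient is attributed to the *first* failing rule. The
order is a design choice (the rules themselves carry no precedence); fixing
it makes the report conservation identity `n_input = n_kept + Σ counts`
exact and testable. Residency and "surgery outside the regional system" are
modeled as a single boolean flag on the inpatient record, as the registries
needed to distinguish them are not part of the record schema. The imaging
lookback window is `(surgery − 365 d, surgery]`, closed on the right; the
last-biopsy gap threshold excludes strictly greater than 365 days.

## Directly-follows maps

`mine_map` computes the exact directly-follows graph: edges are the adjacent
pairs of each trace (self-loops included), each edge accumulating occurrence
count, case coverage, and the day-gap multiset. Commercial process-mining
tools layer proprietary significance/correlation abstraction on top of this
structure; `caremine` implements the documented observable behaviors —
frequency/performance/mixed views, case-coverage percentages, "instant"
same-day edges, dashed start/end markers, and the importance zoom — as its
compatibility target, not a clone of any tool's internals. Edge percentage
labels denote case coverage by default (fraction of cases containing the
transition at least once); raw occurrence labels are available as an option.
Node labels report coverage percentages rather than absolute counts so maps
of hospitals with very different volumes remain comparable.

Performance statistics over an edge's gap multiset: median (default; the
median of an even-sized multiset is the mean of the central pair), mean, and
total. Negative gaps are impossible by trace ordering and asserted. A zero
value renders as "instant".

### Importance zoom

Given fractions `f_a`, `f_p`: keep the top `ceil(f_a·|A|)` activities by case
coverage (ties by label), then among edges between kept activities the top
`ceil(f_p·|E|)` by occurrences (ties by label pair). Two repair phases then
guarantee that every displayed activity lies on a path from the artificial
start to the artificial end (start/end markers count as connectors):

1. Greedily re-add the highest-ranked dropped edge between kept activities
   that strictly reduces the *reachability deficiency* — the count of kept
   activities not reachable from start plus those not co-reachable to end.
   The deficiency measure (rather than the raw number of disconnected
   activities) is what makes the greedy step sound: one edge on a multi-hop
   repair path lowers the deficiency even when no activity becomes fully
   connected yet, so the loop provably terminates.
2. A tight activity zoom can leave kept activities with no connecting edges
   among themselves at all; any remaining deficient activity is then
   reconnected through shortest paths in the full map, re-adding the
   traversed edges together with their endpoint activities.

The result is always a sub-multigraph of the input (edge statistics are
copied, never recomputed), and `zoom(map, 1, 1)` is the identity. An
alternative reading of path sliders — keeping edges above a significance
percentile — exists in commercial tools; the `ceil(f_p·|E|)` reading used
here is documented as a decision, and published tool-specific maps should not
be expected to reproduce under it.

### DOT rendering

Output is plain DOT text (layout is outside the library contract). Pen
widths scale affinely with the primary edge weight (monotone by
construction); node fill intensity scales with case coverage; mixed-view
secondary labels use a smaller font via HTML-like labels.

## Performance and cost statistics

Percentiles (medians, IQRs) use linear interpolation between order
statistics throughout, so reported quartiles are reproducible bit-for-bit.
The 30-day adherence statistic is the per-hospital fraction of cases with
last-biopsy-to-surgery interval ≤ 30 days (closed threshold).

Per-patient cost distributions **include patients with zero services of a
category**; otherwise `mean_cost × n_patients` would not equal the observed
category spend, an identity the tests enforce exactly. The SD is the sample
(n−1) standard deviation, 0 for a single patient. Frequency is category
events divided by patients; `types` counts distinct observed tariff codes.
The mean total cost per patient is the sum of category means and
algebraically equals grand spend over patients. Costs are expressed in
scaled standardized euros via a configurable multiplier (default 1) recorded
on the summary; all cost outputs are homogeneous of degree 1 in the tariffs.

One known representational limit: published per-hospital tables sometimes
show visit columns with median = mean or SD = 0, which no per-patient
distribution containing zeros and repeats can produce; `caremine` implements
the stated per-patient definition and does not attempt to reverse-engineer
such cells.

## Synthetic study conditions

The generator emulates what the analysis assumes about regional
administrative extracts, not any particular published cohort:

- **Waiting times** between consecutive activities are log-normal on day
  gaps, parameterized by target median (days) and geometric SD, rounded to
  whole days. The law is a modeling choice: reported waiting-time IQRs are
  wide and right-skewed, and a two-parameter multiplicative law is the
  simplest that reproduces that shape. Demo defaults use geometric SD 1.8
  (heavy tails, e.g. biopsy→surgery median 45 d); the parameter-recovery
  calibration profile uses 1.4, fixed prospectively so that the ±2-day
  recovery band at n = 1000 corresponds to ≈3.8 standard errors of the
  sample median.
- **Motifs** are per-patient Bernoulli draws: direct biopsy→surgery
  processes (default 2–22% across demo hospitals, the upper value matching
  the scale of short-process fractions reported for low-volume providers),
  same-day mammography+ultrasound clusters, exam repetitions, and breast
  visit loops (up to 3 repeats). Direct-motif patients receive screening
  mammography and a confirmation biopsy *before* the final biopsy, so they
  satisfy the imaging eligibility rule while keeping the last-biopsy→surgery
  transition exam-free.
- **Tariff catalog**: four biopsy variants with costs spanning 0.71–45 s€
  drawn with geometrically decaying weights favouring cheap variants, which
  makes per-patient biopsy cost right-skewed (mean ≫ median); 3 mammography,
  2 ultrasound and 2 visit codes. Demo volumes (120/110/50/20 patients)
  mirror the heterogeneity of high- vs low-volume providers at desk scale.
- **Exclusion injection** mutates an otherwise-clean patient (clearing the
  priority field, duplicating the surgery admission, deleting biopsy or
  imaging rows, or back-dating biopsies past the 365-day window) rather than
  sampling a separate population, so each violator fails *exactly one* rule
  and the exclusion report can be checked against the injection ledger
  exactly. At most one rule is injected per patient, tried in attribution
  order. Default demo rates: 2% per rule.
- Dates are whole calendar days from a fixed origin (default 2018-01-01);
  no time zones or leap handling.

What passing tests on these conditions show: the pipeline's *identities and
contracts* (windowing guarantees, conservation, cost identities, oracle
equivalence of the miner, zoom connectivity) hold on data with realistic
structure, and configured waiting-time medians are recovered through the full
pipeline within ±2 days at n = 1000. What they do not show: anything about
coding quality, linkage errors, truly missing modalities, or the particular
cost/duration values of any real regional cohort — the generator is not
calibrated to reproduce published tables, which derive from confidential
data.

## Problem sizes and determinism

Test and acceptance runs use desk-scale cohorts: 300-patient demo conditions
for pipeline tests, 1000 patients for the parameter-recovery and forced
biopsy-frequency checks, 100 random small logs for miner-oracle equivalence,
and a 4×4 zoom-fraction grid over 20 random maps. All randomness flows
through one seeded NumPy generator per cohort; identical configurations give
byte-identical record streams and identical artifact manifests (content
hashes). Hospital anonymization (H1…Hn by decreasing kept-case volume, ties
by id) happens at report time with a sidecar mapping file.

## Known limitations

- Exclusion attribution depends on the fixed rule order; per-rule counts are
  not comparable with pipelines that attribute differently (overlap between
  rules is resolved, not reported).
- The priority-before/after-residency ordering in the original extraction
  workflow is unknowable from the schema; the fixed order here is a
  convention.
- XES output covers the attributes this pipeline uses (case id, activity,
  midnight timestamps, hospital, tariff, cost); it is standard-conformant
  but not a general-purpose XES library.
- The zoom's path-fraction semantics (`ceil(f_p·|E|)` of ranked edges) is
  one of several defensible readings of slider-based filtering.
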