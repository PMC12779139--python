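"""Synthetic administrative cohort generator.

Emulates the statistical structure of regional inpatient/outpatient
administrative data for the biopsy-to-surgery segment of the breast-cancer
pathway: hospitals of heterogeneous volume, four biopsy tariff variants with
right-skewed costs, mono/bilateral imaging, breast visits with repetitions,
same-day exam clusters, log-normal waiting times between activities, and
controlled injection of violations of each cohort exclusion rule.

Every clean generated patient has exactly one qualifying surgery admission,
at least one biopsy before surgery, at least one imaging exam (mammography or
ultrasound) within 365 days before surgery, a surgical priority class,
in-region residence, and a last-biopsy-to-surgery gap of at most 365 days.
A patient selected for injection of exclusion rule *r* violates exactly rule
*r* and no other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import yaml

from .catalog import (
    ACT_BIOPSY,
    ACT_MAMMOGRAPHY,
    ACT_ULTRASOUND,
    ACT_VISIT,
    BCT,
    BIOPSY,
    MAMMOGRAPHY,
    MASTECTOMY,
    RECONSTRUCTION,
    SURGERY_TYPES,
    TariffCatalog,
    TariffEntry,
    ULTRASOUND,
    VISIT,
    build_default_catalog,
)
from .records import InpatientRecord, OutpatientRecord, PRIORITY_HIGHEST

#: Pseudo-activity used as transition target for any of the three surgery classes.
SURGERY_KEY = "Surgery"

#: Exclusion rules, in the order both injection and downstream attribution use.
EXCLUSION_RULES = (
    "out_of_region",
    "multiple_surgeries",
    "missing_priority",
    "no_biopsy",
    "no_imaging",
    "over_365_days",
)

#: Breast-cancer diagnosis codes the generator draws from (ICD-9-CM:
#: 174.x malignant, 233.0 in situ).
_DX_CODES = ("174.9", "174.8", "174.4", "174.2", "233.0")


@dataclass
class GapDistribution:
    """Waiting-time law for one activity transition.

    Day gaps are log-normal, parameterized by the target *median* in days and
    a *geometric SD* (multiplicative dispersion), then rounded to whole days —
    a right-skewed law with long upper tails, as administrative waiting times
    show.  ``median_days = 0`` degenerates to an instant transition.
    """

    median_days: float
    geometric_sd: float = 1.8

    def validate(self, where: str) -> None:
        if self.median_days < 0:
            raise ValueError(f"{where}.median_days must be >= 0")
        if self.geometric_sd < 1.0:
            raise ValueError(f"{where}.geometric_sd must be >= 1")

    def sample(self, rng: np.random.Generator) -> int:
        if self.median_days <= 0:
            return 0
        x = self.median_days * math.exp(
            math.log(self.geometric_sd) * rng.standard_normal()
        )
        return max(0, int(round(x)))


@dataclass
class MotifProbs:
    """Per-patient probabilities of the pathway motifs the analysis must
    exercise: the short biopsy-straight-to-surgery process, repeated breast
    visits, same-day mammography+ultrasound clusters, and exam repetitions."""

    direct_surgery: float = 0.10
    visit_loop: float = 0.40
    sameday_cluster: float = 0.35
    exam_repeat: float = 0.15

    def validate(self, where: str) -> None:
        for name in ("direct_surgery", "visit_loop", "sameday_cluster", "exam_repeat"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{where}.{name} must be in [0, 1]")


def default_gap_dists() -> dict[tuple[str, str], GapDistribution]:
    """Default transition waiting-time laws (medians in days)."""
    return {
        (ACT_BIOPSY, ACT_MAMMOGRAPHY): GapDistribution(7),
        (ACT_MAMMOGRAPHY, ACT_BIOPSY): GapDistribution(6),
        (ACT_BIOPSY, SURGERY_KEY): GapDistribution(45),
        (ACT_MAMMOGRAPHY, ACT_MAMMOGRAPHY): GapDistribution(10),
        (ACT_MAMMOGRAPHY, ACT_VISIT): GapDistribution(14),
        (ACT_VISIT, ACT_VISIT): GapDistribution(15),
        (ACT_VISIT, SURGERY_KEY): GapDistribution(27),
    }


@dataclass
class HospitalProfile:
    """Volume, motif mix, waiting-time laws and surgery mix of one hospital."""

    hospital_id: str
    n_patients: int
    motif_probs: MotifProbs = field(default_factory=MotifProbs)
    transition_gap_dists: dict[tuple[str, str], GapDistribution] = field(
        default_factory=default_gap_dists
    )
    surgery_mix: dict[str, float] = field(
        default_factory=lambda: {BCT: 0.66, MASTECTOMY: 0.24, RECONSTRUCTION: 0.10}
    )

    def validate(self, where: str = "hospital") -> None:
        if self.n_patients < 0:
            raise ValueError(f"{where}.n_patients must be >= 0")
        self.motif_probs.validate(f"{where}.motif_probs")
        for key, dist in self.transition_gap_dists.items():
            dist.validate(f"{where}.transition_gap_dists[{key}]")
        for stype, p in self.surgery_mix.items():
            if stype not in SURGERY_TYPES:
                raise ValueError(f"{where}.surgery_mix has unknown type {stype!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{where}.surgery_mix[{stype}] must be in [0, 1]")
        if abs(sum(self.surgery_mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"{where}.surgery_mix must sum to 1")

    def gap(self, src: str, tgt: str, rng: np.random.Generator) -> int:
        dist = self.transition_gap_dists.get((src, tgt))
        if dist is None:
            dist = GapDistribution(10)  # fallback for unconfigured transitions
        return dist.sample(rng)


@dataclass
class GeneratorConfig:
    """Full study-condition specification for one synthetic cohort."""

    hospitals: list[HospitalProfile]
    catalog: TariffCatalog = field(default_factory=build_default_catalog)
    exclusion_injection_rates: dict[str, float] = field(default_factory=dict)
    date_origin: date = date(2018, 1, 1)
    seed: int = 0

    def validate(self) -> None:
        if not self.hospitals:
            raise ValueError("hospitals must contain at least one profile")
        for i, h in enumerate(self.hospitals):
            h.validate(f"hospitals[{i}]")
        for rule, rate in self.exclusion_injection_rates.items():
            if rule not in EXCLUSION_RULES:
                raise ValueError(
                    f"exclusion_injection_rates has unknown rule {rule!r}"
                )
            if not 0.0 <= rate <= 1.0:
                raise ValueError(
                    f"exclusion_injection_rates[{rule!r}] must be in [0, 1]"
                )


@dataclass(frozen=True)
class PlannedService:
    """One dated service of a planned patient trajectory, in days relative to
    the patient's first biopsy."""

    day: int
    activity: str  # activity label, or SURGERY_KEY for the surgery
    tariff_code: str | None
    surgery_type: str | None = None


@dataclass
class SyntheticCohort:
    """Generated record streams plus the injection ledger mapping each
    mutated patient to the single exclusion rule it violates."""

    inpatient: list[InpatientRecord]
    outpatient: list[OutpatientRecord]
    injections: dict[str, str]


def _pick_code(
    catalog: TariffCatalog, category: str, rng: np.random.Generator
) -> str:
    """Draw a tariff code within a category, favouring cheaper variants
    geometrically (volume concentrates on simple procedures, producing
    right-skewed per-patient cost distributions)."""
    codes = sorted(catalog.codes(category), key=catalog.cost_of)
    w = np.array([0.5**i for i in range(len(codes))])
    return codes[rng.choice(len(codes), p=w / w.sum())]


def generate_trace(
    profile: HospitalProfile,
    catalog: TariffCatalog,
    rng: np.random.Generator,
) -> list[PlannedService]:
    """Plan one patient's dated activity sequence.

    The sequence is chronologically nondecreasing, begins with a biopsy and
    ends with exactly one surgery drawn from the hospital's surgery mix.
    With probability ``motif_probs.direct_surgery`` the patient follows the
    short process (surgery directly after the last biopsy, the diagnostic
    imaging having preceded that confirmation biopsy); otherwise the patient
    goes through imaging and breast visits, with optional same-day
    ultrasound clusters, exam repetitions and visit loops.
    """
    m = profile.motif_probs
    events: list[PlannedService] = []

    def svc(day: int, activity: str, category: str) -> None:
        events.append(PlannedService(day, activity, _pick_code(catalog, category, rng)))

    svc(0, ACT_BIOPSY, BIOPSY)
    if rng.random() < m.direct_surgery:
        # screening mammography then confirmation biopsy then straight to surgery
        d1 = profile.gap(ACT_BIOPSY, ACT_MAMMOGRAPHY, rng)
        svc(d1, ACT_MAMMOGRAPHY, MAMMOGRAPHY)
        d2 = d1 + max(1, profile.gap(ACT_MAMMOGRAPHY, ACT_BIOPSY, rng))
        svc(d2, ACT_BIOPSY, BIOPSY)
        d3 = d2 + profile.gap(ACT_BIOPSY, SURGERY_KEY, rng)
        surgery_day = d3
    else:
        cur = 0
        if rng.random() < m.sameday_cluster:
            svc(0, ACT_ULTRASOUND, ULTRASOUND)
        cur += profile.gap(ACT_BIOPSY, ACT_MAMMOGRAPHY, rng)
        svc(cur, ACT_MAMMOGRAPHY, MAMMOGRAPHY)
        if rng.random() < m.sameday_cluster:
            svc(cur, ACT_ULTRASOUND, ULTRASOUND)
        if rng.random() < m.exam_repeat:
            cur += profile.gap(ACT_MAMMOGRAPHY, ACT_MAMMOGRAPHY, rng)
            svc(cur, ACT_MAMMOGRAPHY, MAMMOGRAPHY)
        cur += profile.gap(ACT_MAMMOGRAPHY, ACT_VISIT, rng)
        svc(cur, ACT_VISIT, VISIT)
        loops = 0
        while loops < 3 and rng.random() < m.visit_loop:
            cur += profile.gap(ACT_VISIT, ACT_VISIT, rng)
            svc(cur, ACT_VISIT, VISIT)
            loops += 1
        surgery_day = cur + profile.gap(ACT_VISIT, SURGERY_KEY, rng)

    stype = [BCT, MASTECTOMY, RECONSTRUCTION][
        rng.choice(3, p=[profile.surgery_mix.get(t, 0.0) for t in (BCT, MASTECTOMY, RECONSTRUCTION)])
    ]
    events.append(PlannedService(surgery_day, SURGERY_KEY, None, surgery_type=stype))
    return events


def _draw_injection(
    rates: dict[str, float], rng: np.random.Generator
) -> str | None:
    """Assign at most one exclusion rule to a patient: rules are tried in the
    fixed attribution order and the first Bernoulli success wins (so a rate of
    1.0 on a single rule marks every patient with that rule)."""
    for rule in EXCLUSION_RULES:
        rate = rates.get(rule, 0.0)
        if rate > 0 and rng.random() < rate:
            return rule
    return None


def _materialize_patient(
    pid: str,
    profile: HospitalProfile,
    catalog: TariffCatalog,
    origin: date,
    trace: list[PlannedService],
    rng: np.random.Generator,
) -> tuple[list[InpatientRecord], list[OutpatientRecord], date]:
    """Turn a planned trajectory into dated administrative records."""
    start = origin + timedelta(days=int(rng.integers(0, 260)))
    surgery = trace[-1]
    surgery_date = start + timedelta(days=surgery.day)
    admission = surgery_date - timedelta(days=int(rng.integers(0, 2)))
    discharge = surgery_date + timedelta(days=int(rng.integers(1, 5)))
    proc_codes = catalog.procedure_codes(surgery.surgery_type)
    inp = [
        InpatientRecord(
            patient_id=pid,
            hospital_id=profile.hospital_id,
            admission_date=admission,
            discharge_date=discharge,
            principal_dx=_DX_CODES[int(rng.integers(0, len(_DX_CODES)))],
            secondary_dx="",
            procedure_code=proc_codes[int(rng.integers(0, len(proc_codes)))],
            procedure_date=surgery_date,
            priority=PRIORITY_HIGHEST,
            resident_flag=True,
        )
    ]
    out = [
        OutpatientRecord(
            patient_id=pid,
            provider_id=profile.hospital_id,
            service_date=start + timedelta(days=s.day),
            tariff_code=s.tariff_code,
            cost=catalog.cost_of(s.tariff_code),
        )
        for s in trace
        if s.activity != SURGERY_KEY
    ]
    return inp, out, surgery_date


def _inject_violation(
    rule: str,
    inp: list[InpatientRecord],
    out: list[OutpatientRecord],
    surgery_date: date,
    catalog: TariffCatalog,
    rng: np.random.Generator,
) -> tuple[list[InpatientRecord], list[OutpatientRecord]]:
    """Mutate an otherwise-clean patient so it violates exactly ``rule``."""
    rec = inp[0]
    if rule == "out_of_region":
        inp = [replace(rec, resident_flag=False)]
    elif rule == "missing_priority":
        inp = [replace(rec, priority=None)]
    elif rule == "multiple_surgeries":
        second_date = surgery_date + timedelta(days=40)
        inp = inp + [
            replace(
                rec,
                admission_date=second_date,
                discharge_date=second_date + timedelta(days=3),
                procedure_date=second_date,
            )
        ]
    elif rule == "no_biopsy":
        out = [r for r in out if catalog.category_of(r.tariff_code) != BIOPSY]
    elif rule == "no_imaging":
        out = [
            r
            for r in out
            if catalog.category_of(r.tariff_code) not in (MAMMOGRAPHY, ULTRASOUND)
        ]
    elif rule == "over_365_days":
        # push all biopsies back so the last-biopsy -> surgery gap exceeds 365
        # days while imaging stays inside the one-year lookback
        biopsy_dates = [
            r.service_date
            for r in out
            if catalog.category_of(r.tariff_code) == BIOPSY
        ]
        last = max(biopsy_dates)
        shift = (last - (surgery_date - timedelta(days=366 + int(rng.integers(0, 60))))).days
        out = [
            replace(r, service_date=r.service_date - timedelta(days=shift))
            if catalog.category_of(r.tariff_code) == BIOPSY
            else r
            for r in out
        ]
    else:  # pragma: no cover
        raise ValueError(f"unknown exclusion rule {rule!r}")
    return inp, out


def generate_labeled_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the two record streams plus the injection ledger.

    Reproducible: identical config (including seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    inpatient: list[InpatientRecord] = []
    outpatient: list[OutpatientRecord] = []
    injections: dict[str, str] = {}
    counter = 0
    for profile in config.hospitals:
        for _ in range(profile.n_patients):
            pid = f"P{counter:06d}"
            counter += 1
            trace = generate_trace(profile, config.catalog, rng)
            inp, out, surgery_date = _materialize_patient(
                pid, profile, config.catalog, config.date_origin, trace, rng
            )
            rule = _draw_injection(config.exclusion_injection_rates, rng)
            if rule is not None:
                inp, out = _inject_violation(
                    rule, inp, out, surgery_date, config.catalog, rng
                )
                injections[pid] = rule
            inpatient.extend(inp)
            outpatient.extend(out)
    return SyntheticCohort(inpatient, outpatient, injections)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[InpatientRecord], list[OutpatientRecord]]:
    """Generate the inpatient and outpatient record streams."""
    cohort = generate_labeled_cohort(config)
    return cohort.inpatient, cohort.outpatient


def default_config(seed: int = 42, scale: float = 1.0) -> GeneratorConfig:
    """Demonstration study conditions: four hospitals of heterogeneous volume
    and practice style.  ``scale`` multiplies patient volumes (rounded)."""

    def n(x: int) -> int:
        return max(1, int(round(x * scale)))

    hospitals = [
        HospitalProfile(
            "HOSP-A",
            n(120),
            MotifProbs(direct_surgery=0.21, visit_loop=0.30, sameday_cluster=0.40, exam_repeat=0.15),
        ),
        HospitalProfile(
            "HOSP-B",
            n(110),
            MotifProbs(direct_surgery=0.02, visit_loop=0.60, sameday_cluster=0.45, exam_repeat=0.20),
        ),
        HospitalProfile(
            "HOSP-C",
            n(50),
            MotifProbs(direct_surgery=0.02, visit_loop=0.45, sameday_cluster=0.30, exam_repeat=0.10),
            surgery_mix={BCT: 0.80, MASTECTOMY: 0.15, RECONSTRUCTION: 0.05},
        ),
        HospitalProfile(
            "HOSP-D",
            n(20),
            MotifProbs(direct_surgery=0.22, visit_loop=0.30, sameday_cluster=0.30, exam_repeat=0.10),
            surgery_mix={BCT: 0.50, MASTECTOMY: 0.35, RECONSTRUCTION: 0.15},
        ),
    ]
    rates = {rule: 0.02 for rule in EXCLUSION_RULES}
    return GeneratorConfig(hospitals=hospitals, exclusion_injection_rates=rates, seed=seed)


# ---------------------------------------------------------------------------
# YAML round-trip for GeneratorConfig


def _gap_key(key: tuple[str, str]) -> str:
    return f"{key[0]} -> {key[1]}"


def _parse_gap_key(s: str) -> tuple[str, str]:
    src, _, tgt = s.partition("->")
    return src.strip(), tgt.strip()


def config_to_dict(config: GeneratorConfig) -> dict:
    return {
        "seed": config.seed,
        "date_origin": config.date_origin.isoformat(),
        "exclusion_injection_rates": dict(config.exclusion_injection_rates),
        "catalog": {
            "entries": [
                {"code": e.code, "category": e.category, "cost": e.cost}
                for e in config.catalog.entries
            ],
            "surgery_codes": [list(sc) for sc in config.catalog.surgery_codes],
        },
        "hospitals": [
            {
                "hospital_id": h.hospital_id,
                "n_patients": h.n_patients,
                "motif_probs": {
                    "direct_surgery": h.motif_probs.direct_surgery,
                    "visit_loop": h.motif_probs.visit_loop,
                    "sameday_cluster": h.motif_probs.sameday_cluster,
                    "exam_repeat": h.motif_probs.exam_repeat,
                },
                "transition_gap_dists": {
                    _gap_key(k): {
                        "median_days": d.median_days,
                        "geometric_sd": d.geometric_sd,
                    }
                    for k, d in h.transition_gap_dists.items()
                },
                "surgery_mix": dict(h.surgery_mix),
            }
            for h in config.hospitals
        ],
    }


def config_from_dict(d: dict) -> GeneratorConfig:
    catalog = build_default_catalog()
    if "catalog" in d:
        catalog = TariffCatalog(
            entries=[
                TariffEntry(e["code"], e["category"], float(e["cost"]))
                for e in d["catalog"]["entries"]
            ],
            surgery_codes=[tuple(sc) for sc in d["catalog"]["surgery_codes"]],
        )
    hospitals = [
        HospitalProfile(
            hospital_id=h["hospital_id"],
            n_patients=int(h["n_patients"]),
            motif_probs=MotifProbs(**h.get("motif_probs", {})),
            transition_gap_dists={
                _parse_gap_key(k): GapDistribution(
                    float(v["median_days"]), float(v.get("geometric_sd", 1.8))
                )
                for k, v in h.get("transition_gap_dists", {}).items()
            }
            or default_gap_dists(),
            surgery_mix=h.get(
                "surgery_mix", {BCT: 0.66, MASTECTOMY: 0.24, RECONSTRUCTION: 0.10}
            ),
        )
        for h in d["hospitals"]
    ]
    return GeneratorConfig(
        hospitals=hospitals,
        catalog=catalog,
        exclusion_injection_rates=d.get("exclusion_injection_rates", {}),
        date_origin=date.fromisoformat(d.get("date_origin", "2018-01-01")),
        seed=int(d.get("seed", 0)),
    )


def config_to_yaml(config: GeneratorConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
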