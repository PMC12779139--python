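"""Tariff catalog and activity vocabulary for the breast-cancer surgical pathway.

The analyzed pathway segment runs from cyto-histological diagnosis (biopsy) to
surgery.  Outpatient services are identified by regional tariff codes grouped
into four diagnostic exam categories; inpatient surgical procedures are
identified by ICD-9-CM intervention codes grouped into three surgery classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

# Diagnostic exam categories of the outpatient tariff nomenclator.
BIOPSY = "biopsy"
MAMMOGRAPHY = "mammography"
ULTRASOUND = "ultrasound"
VISIT = "visit"
CATEGORIES = (BIOPSY, MAMMOGRAPHY, ULTRASOUND, VISIT)

# Surgery classes (type of surgical approach).
BCT = "BCT"  # breast-conserving therapy
MASTECTOMY = "mastectomy"
RECONSTRUCTION = "reconstruction"
SURGERY_TYPES = (BCT, MASTECTOMY, RECONSTRUCTION)

# The seven-activity whitelist of the mined event log.
ACT_BIOPSY = "Biopsy"
ACT_MAMMOGRAPHY = "Mammography"
ACT_ULTRASOUND = "Ultrasound"
ACT_VISIT = "Outpatient visit"
ACT_BCT = "BCT"
ACT_MASTECTOMY = "Mastectomy"
ACT_RECONSTRUCTION = "Reconstruction"

SURGERY_LABELS = {
    BCT: ACT_BCT,
    MASTECTOMY: ACT_MASTECTOMY,
    RECONSTRUCTION: ACT_RECONSTRUCTION,
}
CATEGORY_LABELS = {
    BIOPSY: ACT_BIOPSY,
    MAMMOGRAPHY: ACT_MAMMOGRAPHY,
    ULTRASOUND: ACT_ULTRASOUND,
    VISIT: ACT_VISIT,
}
ACTIVITY_WHITELIST = (
    ACT_BIOPSY,
    ACT_MAMMOGRAPHY,
    ACT_ULTRASOUND,
    ACT_VISIT,
    ACT_BCT,
    ACT_MASTECTOMY,
    ACT_RECONSTRUCTION,
)

# Canonical within-day ordering: the records carry day granularity only, so
# same-day ties must be broken deterministically (exams before surgery).
DAY_ORDER = {
    ACT_BIOPSY: 0,
    ACT_MAMMOGRAPHY: 1,
    ACT_ULTRASOUND: 2,
    ACT_VISIT: 3,
    ACT_BCT: 4,
    ACT_MASTECTOMY: 4,
    ACT_RECONSTRUCTION: 4,
}


@dataclass(frozen=True)
class TariffEntry:
    """One outpatient tariff: an opaque code, its exam category, and its cost
    in scaled standardized euros (s€) per service."""

    code: str
    category: str
    cost: float


@dataclass
class TariffCatalog:
    """Lookup table linking outpatient tariff codes to exam categories and
    costs, plus the ICD-9-CM procedure codes the generator may emit per
    surgery class.

    Invariants (checked on construction): tariff codes unique, costs
    nonnegative, categories known.
    """

    entries: list[TariffEntry] = field(default_factory=list)
    surgery_codes: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(codes) != len(set(codes)):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate tariff codes: {dup}")
        for e in self.entries:
            if e.category not in CATEGORIES:
                raise ValueError(f"unknown category {e.category!r} for code {e.code}")
            if e.cost < 0:
                raise ValueError(f"negative cost for code {e.code}")
        for _, stype in self.surgery_codes:
            if stype not in SURGERY_TYPES:
                raise ValueError(f"unknown surgery type {stype!r}")
        self._by_code = {e.code: e for e in self.entries}

    def codes(self, category: str) -> list[str]:
        return [e.code for e in self.entries if e.category == category]

    def category_of(self, code: str) -> str | None:
        e = self._by_code.get(code)
        return e.category if e is not None else None

    def cost_of(self, code: str) -> float:
        return self._by_code[code].cost

    def procedure_codes(self, surgery_type: str) -> list[str]:
        return [c for c, t in self.surgery_codes if t == surgery_type]

    def scaled(self, k: float) -> "TariffCatalog":
        """Return a copy with every tariff cost multiplied by ``k``
        (the s€ scaling factor is a configurable multiplier)."""
        return TariffCatalog(
            entries=[replace(e, cost=e.cost * k) for e in self.entries],
            surgery_codes=list(self.surgery_codes),
        )


def build_default_catalog() -> TariffCatalog:
    """Default tariff catalog emulating a regional nomenclator.

    Four biopsy variants with widely spread costs (the cheap fine-needle
    variants dominate in volume while stereotactic procedures are expensive,
    yielding right-skewed per-patient biopsy cost distributions with
    mean >> median), mono/bilateral (+tomosynthesis) mammography,
    mono/bilateral ultrasound, and first/follow-up breast visits.
    """
    entries = [
        # biopsy variants, ordered cheap -> expensive
        TariffEntry("91.39.4", BIOPSY, 0.71),   # echo-guided fine-needle biopsy
        TariffEntry("91.39.3", BIOPSY, 2.20),   # echo-guided biopsy w/ retroaspiration
        TariffEntry("91.39.2", BIOPSY, 28.00),  # stereotactic microbiopsy
        TariffEntry("91.39.1", BIOPSY, 45.00),  # stereotactic biopsy w/ retroaspiration
        # mammography
        TariffEntry("87.37.1", MAMMOGRAPHY, 1.78),  # monolateral
        TariffEntry("87.37.2", MAMMOGRAPHY, 2.36),  # bilateral
        TariffEntry("87.37.3", MAMMOGRAPHY, 5.45),  # tomosynthesis
        # ultrasound
        TariffEntry("88.73.1", ULTRASOUND, 1.37),  # monolateral
        TariffEntry("88.73.2", ULTRASOUND, 2.47),  # bilateral
        # breast visits
        TariffEntry("89.7A.3", VISIT, 12.97),  # first breast visit
        TariffEntry("89.01.1", VISIT, 5.43),   # follow-up breast visit
    ]
    surgery_codes = [
        ("85.21", BCT),
        ("85.22", BCT),
        ("85.23", BCT),
        ("85.33", RECONSTRUCTION),
        ("85.34", RECONSTRUCTION),
        ("85.35", RECONSTRUCTION),
        ("85.36", RECONSTRUCTION),
        ("85.41", MASTECTOMY),
        ("85.42", MASTECTOMY),
        ("85.43", MASTECTOMY),
    ]
    return TariffCatalog(entries=entries, surgery_codes=surgery_codes)
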