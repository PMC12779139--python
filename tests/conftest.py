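import random
from datetime import date, timedelta

import pytest

from caremine.catalog import (
    ACT_BCT,
    ACT_BIOPSY,
    ACT_MAMMOGRAPHY,
    ACT_MASTECTOMY,
    ACT_ULTRASOUND,
    ACT_VISIT,
    build_default_catalog,
)
from caremine.eventlog import Event, EventLog
from caremine.synthetic import default_config

EXAMS = [ACT_MAMMOGRAPHY, ACT_ULTRASOUND, ACT_VISIT]
SURGERIES = [ACT_BCT, ACT_MASTECTOMY]


@pytest.fixture
def catalog():
    return build_default_catalog()


@pytest.fixture
def demo_config():
    cfg = default_config(seed=11)
    for h in cfg.hospitals:
        h.n_patients = max(10, h.n_patients // 4)
    return cfg


def random_log(rng: random.Random, n_cases: int = 8, max_events: int = 8) -> EventLog:
    """Random well-formed pathway log: biopsy first, surgery last, exams in
    between, nondecreasing dates (used as input to the mining oracle)."""
    t0 = date(2018, 1, 1)
    log = EventLog()
    for i in range(n_cases):
        cid = f"c{i}"
        day = rng.randrange(0, 30)
        events = [Event(cid, ACT_BIOPSY, t0 + timedelta(days=day), "H")]
        for _ in range(rng.randrange(0, max_events - 2)):
            day += rng.randrange(0, 20)
            events.append(Event(cid, rng.choice(EXAMS), t0 + timedelta(days=day), "H"))
        day += rng.randrange(0, 40)
        events.append(Event(cid, rng.choice(SURGERIES), t0 + timedelta(days=day), "H"))
        log.traces[cid] = events
    return log
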