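import pytest

from clutchwork.mc_simulator import DistSpec, SimParams
from clutchwork.records_io import ClutchEvent, CohortLog, IndividualRecord


def record(rid, death, day_size_pairs, censored=False):
    return IndividualRecord(
        id=rid,
        death_day=death,
        censored=censored,
        clutches=[ClutchEvent(day=d, size=s, parent_id=rid) for d, s in day_size_pairs],
    )


@pytest.fixture
def pair_records():
    """Two-animal toy dataset used throughout: A lays twice, B once."""
    return [
        record("A", 142, [(50, 10), (80, 30)]),
        record("B", 120, [(60, 20)]),
    ]


@pytest.fixture
def point_mass_params():
    """Fully deterministic schedule: 3 clutches at days 56/84/112, sizes
    20/50/70, death 30 days after the last clutch."""
    return SimParams(
        label="point_mass",
        zd_c1=DistSpec(56, 0),
        inter_clutch=[DistSpec(28, 0), DistSpec(28, 0)],
        clutch_size=[DistSpec(20, 0), DistSpec(50, 0), DistSpec(70, 0)],
        clutch_count={3: 1.0},
        post_last_survival=DistSpec(30, 0),
        lifespan=DistSpec(200, 0),
    )


@pytest.fixture
def spread_params():
    """Mildly dispersed schedule with rounds separated far beyond the
    within-round day spread (for round-recovery tests)."""
    return SimParams(
        label="spread",
        zd_c1=DistSpec(56, 2, 45, 67),
        inter_clutch=[DistSpec(40, 2, 30, 50), DistSpec(40, 2, 30, 50)],
        clutch_size=[DistSpec(20, 3, 10, 30)] * 3,
        clutch_count={3: 1.0},
        post_last_survival=DistSpec(100, 0),
        lifespan=DistSpec(250, 0),
    )


@pytest.fixture
def simple_cohort():
    """n0=3, one death at day 70, clutches across two bouts."""
    return CohortLog(
        n0=3,
        death_days=[70],
        clutches=[
            ClutchEvent(day=50, size=10),
            ClutchEvent(day=52, size=12),
            ClutchEvent(day=55, size=14),
            ClutchEvent(day=80, size=20),
            ClutchEvent(day=81, size=22),
            ClutchEvent(day=90, size=24),
        ],
    )
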