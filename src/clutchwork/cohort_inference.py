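"""Round assignment and series summaries for interbreeding cohorts.

When animals breed in a group, clutches cannot be attributed to parents.
Under two assumptions — (1) animals raised together breed in rough
synchrony, and (2) every animal in the cohort reproduces — the anonymous
clutch stream can still be partitioned into *reproductive rounds*: the
first round opens with the first clutch and closes once the number of
clutches laid equals the number of animals present at the opening; each
subsequent round opens with the next clutch and closes by the same counting
rule against the number then present.

The rule's known failure modes are deliberate properties of this
implementation, not bugs to smooth over: an animal that dies (or fails to
breed) before laying in a round inflates that round's quota and drags early
next-round clutches into it; a wide temporal spread mixes adjacent rounds.
The synthetic-data module makes both modes measurable against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats as _sps

from .records_io import ClutchEvent, CohortLog, IndividualRecord

__all__ = [
    "RoundSummary",
    "RoundAssignment",
    "DepositionHistogram",
    "CohortSeries",
    "assign_rounds",
    "round_summaries",
    "build_pseudo_cohort",
    "bin_depositions",
    "cohort_series",
]


@dataclass(frozen=True)
class RoundSummary:
    """Per-round aggregate: timing and clutch-size mean with Student-t CIs.

    ``quota`` is the number of animals alive at the round's opening day;
    ``complete`` is True when the round collected its full quota of
    clutches (only the final round may be partial). CIs are ``None`` when
    the round holds fewer than two clutches.
    """

    index: int
    n: int
    quota: int
    complete: bool
    day_mean: float
    day_ci: Optional[tuple[float, float]]
    size_mean: float
    size_ci: Optional[tuple[float, float]]


@dataclass
class RoundAssignment:
    """Partition of a cohort's clutches into rounds (labels are 1-based,
    parallel to ``log.clutches`` in day order, and non-decreasing)."""

    labels: list[int]
    quotas: list[int]
    n_clutches: int

    @property
    def n_rounds(self) -> int:
        return len(self.quotas)


@dataclass(frozen=True)
class DepositionHistogram:
    """Clutch deposition counts in half-open day bins [i*w, (i+1)*w)."""

    width: int
    starts: list[int]
    counts: list[int]


@dataclass(frozen=True)
class CohortSeries:
    """Day-indexed series: animals alive, cumulative clutches, cumulative
    embryos, from day 0 to the last event or death."""

    days: list[int]
    alive: list[int]
    cum_clutches: list[int]
    cum_embryos: list[int]


def assign_rounds(log: CohortLog) -> RoundAssignment:
    """Partition a cohort's clutch stream into reproductive rounds.

    Deterministic and invariant to input row order after the canonical
    stable day sort; a trailing round that never fills its quota is kept
    (marked incomplete by :func:`round_summaries`). A log with zero
    clutches yields an empty assignment.
    """
    clutches = sorted(log.clutches, key=lambda c: c.day)  # stable
    labels: list[int] = []
    quotas: list[int] = []
    i = 0
    r = 0
    while i < len(clutches):
        r += 1
        opening_day = clutches[i].day
        quota = max(log.alive(opening_day), 1)
        take = min(quota, len(clutches) - i)
        labels.extend([r] * take)
        quotas.append(quota)
        i += take
    return RoundAssignment(labels=labels, quotas=quotas, n_clutches=len(clutches))


def _t_ci(values: Sequence[float], level: float) -> Optional[tuple[float, float]]:
    n = len(values)
    if n < 2:
        return None
    m = sum(values) / n
    sd = math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))
    half = _sps.t.ppf(0.5 + level / 2, n - 1) * sd / math.sqrt(n)
    return (m - half, m + half)


def round_summaries(
    assignment: RoundAssignment, log: CohortLog, ci_level: float = 0.95
) -> list[RoundSummary]:
    """Mean day/size and Student-t confidence intervals per round."""
    clutches = sorted(log.clutches, key=lambda c: c.day)
    if len(clutches) != len(assignment.labels):
        raise ValueError(
            f"assignment covers {len(assignment.labels)} clutches "
            f"but log has {len(clutches)}"
        )
    out = []
    for r, quota in enumerate(assignment.quotas, start=1):
        members = [c for c, lab in zip(clutches, assignment.labels) if lab == r]
        days = [float(c.day) for c in members]
        sizes = [float(c.size) for c in members]
        out.append(
            RoundSummary(
                index=r,
                n=len(members),
                quota=quota,
                complete=len(members) == quota,
                day_mean=sum(days) / len(days),
                day_ci=_t_ci(days, ci_level),
                size_mean=sum(sizes) / len(sizes),
                size_ci=_t_ci(sizes, ci_level),
            )
        )
    return out


def build_pseudo_cohort(records: Sequence[IndividualRecord]) -> CohortLog:
    """Pool isolated individuals' records into an anonymized cohort log.

    All records must share the birth-day-0 convention. Clutch and embryo
    totals are conserved; parent attribution is dropped; censored
    individuals contribute no death day.
    """
    if not records:
        raise ValueError("need at least one record")
    deaths = sorted(
        r.death_day for r in records if not r.censored and r.death_day is not None
    )
    merged = [
        ClutchEvent(day=c.day, size=c.size)
        for r in records
        for c in r.clutches
    ]
    merged.sort(key=lambda c: c.day)  # stable tie order
    return CohortLog(
        n0=len(records), death_days=deaths, clutches=merged, label="pseudo-cohort"
    )


def bin_depositions(log: CohortLog, width: int = 5) -> DepositionHistogram:
    """Histogram of clutch events in half-open bins [0,w), [w,2w), ...

    Five-day bins are the conventional display for reproductive synchrony:
    a cohort whose animals lay in tight bouts concentrates each round's
    clutches into one or two adjacent bins.
    """
    if width < 1:
        raise ValueError(f"bin width must be >= 1 day, got {width}")
    if not log.clutches:
        return DepositionHistogram(width=width, starts=[], counts=[])
    last_bin = max(c.day for c in log.clutches) // width
    counts = [0] * (last_bin + 1)
    for c in log.clutches:
        counts[c.day // width] += 1
    return DepositionHistogram(
        width=width, starts=[i * width for i in range(last_bin + 1)], counts=counts
    )


def cohort_series(log: CohortLog) -> CohortSeries:
    """Survival and cumulative production series, day 0 through the last
    recorded event (clutch or death)."""
    horizon = 0
    if log.clutches:
        horizon = max(horizon, max(c.day for c in log.clutches))
    if log.death_days:
        horizon = max(horizon, max(log.death_days))
    days = list(range(horizon + 1))
    alive = [log.alive(d) for d in days]
    cum_c = [0] * (horizon + 1)
    cum_e = [0] * (horizon + 1)
    for c in log.clutches:
        cum_c[c.day] += 1
        cum_e[c.day] += c.size
    for d in range(1, horizon + 1):
        cum_c[d] += cum_c[d - 1]
        cum_e[d] += cum_e[d - 1]
    return CohortSeries(days=days, alive=alive, cum_clutches=cum_c, cum_embryos=cum_e)
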