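"""Per-clutch-number and interval statistics for isolated individuals.

These are the summaries a life-history table reports for an iteroparous
animal observed from birth to death: for each clutch index k, how many
individuals produced a k-th clutch and how large it was; for each pair of
consecutive clutches, how long after birth the later one came (cumulative)
and how far apart the two were (step); and per-individual reproductive
capacity (total young produced over a lifetime).

Conventions
-----------
* Day 0 is the deposition of the zygote the focal animal developed from, so
  the ZD-C1 interval is the egg-to-egg generation time.
* Sample SD uses the n-1 denominator and is reported as ``None`` (absent)
  for singleton samples, matching how printed tables leave such cells bare.
* The step interval between clutches k and k+1 is the mean of per-individual
  differences over individuals possessing *both* clutches — not the
  difference of the two cumulative means, which weights individuals
  differently when the samples differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .records_io import IndividualRecord

__all__ = [
    "ClutchNumberStats",
    "IntervalStats",
    "CapacitySummary",
    "CapacityFromStats",
    "clutch_number_stats",
    "interval_stats",
    "reproductive_capacity",
    "capacity_from_stats",
]


def _mean(xs: Sequence[float]) -> float:
    return sum(xs) / len(xs)


def _sample_sd(xs: Sequence[float]) -> Optional[float]:
    if len(xs) < 2:
        return None
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


@dataclass(frozen=True)
class ClutchNumberStats:
    """Clutch-size statistics for one clutch index (1-based)."""

    k: int
    n: int
    mean: float
    sd: Optional[float]
    min: int
    max: int


@dataclass(frozen=True)
class IntervalStats:
    """Timing statistics for one transition (ZD-C1 or Ck-Ck+1).

    ``cum_*`` are days from birth to the later clutch, over individuals
    possessing it; ``step_*`` are per-individual differences between the two
    consecutive clutches, over individuals possessing both. For ZD-C1 the
    step fields equal the cumulative ones (the earlier event is birth).
    """

    label: str
    n: int
    cum_mean: float
    cum_sd: Optional[float]
    cum_min: int
    cum_max: int
    step_mean: float
    step_sd: Optional[float] = None
    step_min: Optional[int] = None
    step_max: Optional[int] = None


@dataclass(frozen=True)
class CapacitySummary:
    """Lifetime reproductive output of a set of individuals."""

    n_individuals: int
    total: int
    mean: float
    max: int
    clutches_mean: float
    clutches_max: int
    lifespan_mean: Optional[float]
    post_last_clutch_mean: Optional[float]


@dataclass(frozen=True)
class CapacityFromStats:
    total: float
    mean: float


def clutch_number_stats(records: Sequence[IndividualRecord]) -> list[ClutchNumberStats]:
    """Per-clutch-index size statistics (one row per index present)."""
    max_k = max((len(r.clutches) for r in records), default=0)
    rows = []
    for k in range(1, max_k + 1):
        sizes = [r.clutches[k - 1].size for r in records if len(r.clutches) >= k]
        rows.append(
            ClutchNumberStats(
                k=k,
                n=len(sizes),
                mean=_mean(sizes),
                sd=_sample_sd(sizes),
                min=min(sizes),
                max=max(sizes),
            )
        )
    return rows


def interval_stats(records: Sequence[IndividualRecord]) -> list[IntervalStats]:
    """ZD-C1 and inter-clutch timing statistics.

    Raises ``ValueError`` if any record's clutches are out of day order
    (the birth-day-0 convention makes cumulative days meaningful only for
    ordered records).
    """
    for r in records:
        days = [c.day for c in r.clutches]
        if days != sorted(days):
            raise ValueError(f"record {r.id!r}: clutches not in day order")

    max_k = max((len(r.clutches) for r in records), default=0)
    rows: list[IntervalStats] = []
    if max_k == 0:
        return rows

    first_days = [r.clutches[0].day for r in records if r.clutches]
    rows.append(
        IntervalStats(
            label="ZD-C1",
            n=len(first_days),
            cum_mean=_mean(first_days),
            cum_sd=_sample_sd(first_days),
            cum_min=min(first_days),
            cum_max=max(first_days),
            step_mean=_mean(first_days),
            step_sd=_sample_sd(first_days),
            step_min=min(first_days),
            step_max=max(first_days),
        )
    )
    for k in range(1, max_k):
        both = [r for r in records if len(r.clutches) >= k + 1]
        if not both:
            continue
        later = [r.clutches[k].day for r in both]
        steps = [r.clutches[k].day - r.clutches[k - 1].day for r in both]
        rows.append(
            IntervalStats(
                label=f"C{k}-C{k + 1}",
                n=len(both),
                cum_mean=_mean(later),
                cum_sd=_sample_sd(later),
                cum_min=min(later),
                cum_max=max(later),
                step_mean=_mean(steps),
                step_sd=_sample_sd(steps),
                step_min=min(steps),
                step_max=max(steps),
            )
        )
    return rows


def reproductive_capacity(records: Sequence[IndividualRecord]) -> CapacitySummary:
    """Lifetime output summary.

    Zero-clutch individuals count toward the mean's denominator with total
    0. Censored individuals contribute their embryos and clutch counts but
    are excluded from the lifespan and post-last-clutch survival means.
    """
    if not records:
        raise ValueError("need at least one record")
    totals = [r.total_embryos for r in records]
    counts = [len(r.clutches) for r in records]
    lifespans = [r.death_day for r in records if not r.censored and r.death_day is not None]
    post_last = [
        r.death_day - r.last_clutch_day
        for r in records
        if not r.censored and r.death_day is not None and r.clutches
    ]
    return CapacitySummary(
        n_individuals=len(records),
        total=sum(totals),
        mean=sum(totals) / len(records),
        max=max(totals),
        clutches_mean=_mean(counts),
        clutches_max=max(counts),
        lifespan_mean=_mean(lifespans) if lifespans else None,
        post_last_clutch_mean=_mean(post_last) if post_last else None,
    )


def capacity_from_stats(
    stats: Sequence[ClutchNumberStats], n_individuals: int
) -> CapacityFromStats:
    """Mean reproductive capacity reconstructed from a per-clutch-index table.

    ``total = sum_k n_k * mean_k`` is exact when the table's means are exact;
    dividing by the number of individuals gives embryos per individual. This
    is how a lifetime capacity is recovered from a printed summary table when
    the raw per-animal records are not available.
    """
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    total = sum(row.n * row.mean for row in stats)
    return CapacityFromStats(total=total, mean=total / n_individuals)
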