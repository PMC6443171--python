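"""Monte Carlo simulator of individual reproductive schedules.

Each simulated animal draws a clutch count m from a categorical
distribution, a zygote-to-first-clutch time, m-1 inter-clutch intervals, m
clutch sizes, and a post-last-clutch survival time (or, for m = 0, a
lifespan). Draws come from truncated normal distributions whose truncated
mean and SD are calibrated to match the reported moments (see
:class:`DistSpec`), then rounded to integer days / embryo counts.

Individuals are independent — there is no interaction or coordination
between animals in a simulated cohort. That independence is the point of
the model: it is the null hypothesis against which observed cohort-wide
clustering of egg laying is judged. Because the variance of a sum of
independent intervals accumulates, simulated cohorts lose synchrony after
the first round even when real cohorts do not.

Reproducibility: every stochastic entry point takes a seed (or Generator);
per-individual substreams are derived by counter (run index, individual
index), so changing ``n`` or ``runs`` never reshuffles the draws of other
individuals.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import optimize
from scipy import stats as _sps
from scipy.special import ndtr as _ndtr, ndtri as _ndtri

from .cohort_inference import assign_rounds, build_pseudo_cohort, round_summaries
from .lifehist import clutch_number_stats, interval_stats, reproductive_capacity
from .records_io import ClutchEvent, CohortLog, IndividualRecord

__all__ = [
    "DistSpec",
    "SimParams",
    "MetricSummary",
    "ReplicateSummary",
    "EstimationError",
    "categorical_from_survival_counts",
    "estimate_params_from_individuals",
    "estimate_params_from_cohort",
    "simulate_individual",
    "simulate_cohort",
    "run_replicates",
]


class EstimationError(ValueError):
    """Parameters cannot be identified from the given data."""


@dataclass(frozen=True)
class DistSpec:
    """A reported (mean, SD, min, max) quadruple and its generative law.

    Sampling law: a normal distribution truncated to ``[min, max]``. The
    reported mean/SD are moments of the *bounded* data, so the parent
    (mu, sigma) are calibrated (least squares on the truncated moments,
    mean weighted heavily) so that the truncated distribution reproduces
    them; naive truncation of N(mean, sd) would bias the mean by up to a
    couple of days for asymmetric bounds. When the reported SD exceeds the
    family's supremum on the support (the uniform limit (max-min)/sqrt(12))
    the calibrated SD saturates below the target while the mean still
    matches. ``sd = 0`` or ``min == max`` degenerates to a point mass.
    """

    mean: float
    sd: float
    min: Optional[float] = None
    max: Optional[float] = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.min is not None and self.max is not None:
            if not (self.min <= self.mean <= self.max):
                raise ValueError(
                    f"mean {self.mean} outside bounds [{self.min}, {self.max}]"
                )

    @property
    def degenerate(self) -> bool:
        return self.sd == 0 or (
            self.min is not None and self.max is not None and self.min == self.max
        )

    def sample(self, rng: np.random.Generator) -> float:
        """One draw from the (calibrated) truncated normal."""
        if self.degenerate:
            return self.mean
        if self.min is None and self.max is None:
            return float(rng.normal(self.mean, self.sd))
        mu, sigma, upper_tail, p_lo, p_hi = _sampler_constants(
            self.mean,
            self.sd,
            self.min if self.min is not None else -np.inf,
            self.max if self.max is not None else np.inf,
        )
        # inverse-CDF draw: deterministic under rng and immune to the low
        # acceptance rates a rejection loop would hit for tail-tilted parents.
        # When the support lies in the parent's upper tail the CDF values
        # round to 1.0, so the draw runs in survival-function space there.
        u = rng.uniform()
        if upper_tail:
            q = p_lo - u * (p_lo - p_hi)
            q = max(q, 5e-324)
            x = mu - sigma * float(_ndtri(q))
        else:
            p = p_lo + u * (p_hi - p_lo)
            p = max(p, 5e-324)
            x = mu + sigma * float(_ndtri(p))
        if self.min is not None:
            x = max(x, self.min)
        if self.max is not None:
            x = min(x, self.max)
        return x

    def to_json(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    @classmethod
    def from_json(cls, obj: Mapping) -> "DistSpec":
        return cls(
            mean=float(obj["mean"]),
            sd=float(obj.get("sd", 0.0)),
            min=obj.get("min"),
            max=obj.get("max"),
        )


@functools.lru_cache(maxsize=512)
def _sampler_constants(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float, bool, float, float]:
    """Parent (mu, sigma) and bound probabilities for inverse-CDF draws.

    Returns CDF values at the bounds, or survival-function values when the
    support sits in the parent's upper tail (where the CDF has no
    precision left).
    """
    mu, sigma = _calibrate(mean, sd, lo, hi)
    a = (lo - mu) / sigma if np.isfinite(lo) else -np.inf
    b = (hi - mu) / sigma if np.isfinite(hi) else np.inf
    upper_tail = (a + min(b, a + 100)) / 2 > 0
    if upper_tail:
        sf_lo = float(_ndtr(-a)) if np.isfinite(a) else 1.0
        sf_hi = float(_ndtr(-b)) if np.isfinite(b) else 0.0
        return mu, sigma, True, sf_lo, sf_hi
    cdf_lo = float(_ndtr(a)) if np.isfinite(a) else 0.0
    cdf_hi = float(_ndtr(b)) if np.isfinite(b) else 1.0
    return mu, sigma, False, cdf_lo, cdf_hi


@functools.lru_cache(maxsize=512)
def _calibrate(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-truncation best matches (mean, sd).

    Mean residual is weighted 50x over the SD residual: the mean is always
    attainable on the support, the SD sometimes is not.
    """
    # finite anchors for the optimizer box only; moments use the true bounds
    lo_f = lo if np.isfinite(lo) else mean - 12 * sd
    hi_f = hi if np.isfinite(hi) else mean + 12 * sd
    span = hi_f - lo_f

    def resid(x):
        mu, logs = x
        s = math.exp(logs)
        a = (lo - mu) / s if np.isfinite(lo) else -np.inf
        b = (hi - mu) / s if np.isfinite(hi) else np.inf
        m, v = _sps.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        if not (np.isfinite(m) and np.isfinite(v)):
            return [1e6, 1e6]
        return [50.0 * (m - mean) / max(sd, 1e-9), (math.sqrt(v) - sd) / max(sd, 1e-9)]

    best = None
    for x0 in (
        [mean, math.log(sd)],
        [(lo_f + hi_f) / 2.0, math.log(max(span, 1e-6))],
        [mean, math.log(max(2 * span, 1e-6))],
    ):
        try:
            r = optimize.least_squares(
                resid,
                x0,
                bounds=(
                    [lo_f - 3 * span, math.log(sd) - 3],
                    [hi_f + 3 * span, math.log(max(3 * span, 2 * sd))],
                ),
            )
        except Exception:
            continue
        if best is None or r.cost < best.cost:
            best = r
    if best is None:  # fall back to the uncalibrated parent
        return mean, sd
    return float(best.x[0]), float(math.exp(best.x[1]))


@dataclass
class SimParams:
    """Complete parameter set for the schedule simulator.

    ``inter_clutch[k-1]`` governs the transition from clutch k to k+1;
    ``clutch_size[k-1]`` the size of clutch k; ``clutch_count`` maps a
    clutch count to its probability; ``lifespan`` is used only for animals
    that never lay (otherwise death = last clutch day + post-last survival).
    """

    label: str
    zd_c1: DistSpec
    inter_clutch: list[DistSpec]
    clutch_size: list[DistSpec]
    clutch_count: dict[int, float]
    post_last_survival: DistSpec
    lifespan: DistSpec
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.clutch_count.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"clutch_count probabilities sum to {total}, not 1")
        self.validate_reachable()

    def validate_reachable(self) -> None:
        """Fail fast if any reachable clutch count lacks a spec."""
        for m, p in self.clutch_count.items():
            if p <= 0:
                continue
            if m > len(self.clutch_size):
                raise ValueError(
                    f"clutch count {m} reachable but only "
                    f"{len(self.clutch_size)} clutch_size specs defined"
                )
            if m >= 2 and m - 1 > len(self.inter_clutch):
                raise ValueError(
                    f"clutch count {m} reachable but only "
                    f"{len(self.inter_clutch)} inter_clutch specs defined"
                )

    @property
    def max_count(self) -> int:
        return max((m for m, p in self.clutch_count.items() if p > 0), default=0)

    def to_json(self) -> dict:
        return {
            "label": self.label,
            "zd_c1": self.zd_c1.to_json(),
            "inter_clutch": [d.to_json() for d in self.inter_clutch],
            "clutch_size": [d.to_json() for d in self.clutch_size],
            "clutch_count": {str(k): v for k, v in sorted(self.clutch_count.items())},
            "post_last_survival": self.post_last_survival.to_json(),
            "lifespan": self.lifespan.to_json(),
            "notes": self.notes,
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "SimParams":
        return cls(
            label=str(obj.get("label", "")),
            zd_c1=DistSpec.from_json(obj["zd_c1"]),
            inter_clutch=[DistSpec.from_json(d) for d in obj.get("inter_clutch", [])],
            clutch_size=[DistSpec.from_json(d) for d in obj.get("clutch_size", [])],
            clutch_count={int(k): float(v) for k, v in obj["clutch_count"].items()},
            post_last_survival=DistSpec.from_json(obj["post_last_survival"]),
            lifespan=DistSpec.from_json(obj["lifespan"]),
            notes=dict(obj.get("notes", {})),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2) + "\n", "utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SimParams":
        return cls.from_json(json.loads(Path(path).read_text("utf-8")))


def categorical_from_survival_counts(
    s_counts: Sequence[int], n_individuals: int
) -> dict[int, float]:
    """Clutch-count distribution from per-index sample sizes S_1..S_K.

    If S_k individuals produced a k-th clutch, then S_k - S_{k+1} produced
    exactly k. Observed S columns can be non-monotone (a first clutch can
    be missed while later ones are recorded), so negative differences are
    clipped to zero; P(0) absorbs the individuals left unaccounted for,
    max(N - max_k S_k, 0).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    s = list(s_counts) + [0]
    weights = {k: max(s[k - 1] - s[k], 0) for k in range(1, len(s))}
    weights = {k: w for k, w in weights.items() if w > 0}
    w0 = max(n_individuals - max(s_counts, default=0), 0)
    if w0 > 0:
        weights[0] = w0
    total = sum(weights.values())
    if total == 0:
        raise EstimationError("no individuals accounted for in S counts")
    return {k: w / total for k, w in sorted(weights.items())}


def _spec_from_values(values: Sequence[float]) -> DistSpec:
    m = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else 0.0
    return DistSpec(mean=m, sd=sd, min=float(min(values)), max=float(max(values)))


def estimate_params_from_individuals(
    records: Sequence[IndividualRecord], label: str = "from_individuals"
) -> SimParams:
    """Moment estimates from fully-attributed individual records.

    Every DistSpec is (mean, sample SD, min, max) of the directly observed
    quantity; clutch_count is the empirical categorical over per-individual
    clutch counts. Metrics with no observations are omitted, and a later
    simulation that needs them fails fast.
    """
    if len(records) < 2:
        raise EstimationError("need >= 2 records for sample SDs")
    ivals = interval_stats(records)
    if not ivals:
        raise EstimationError("no clutches in any record")
    zd = next(r for r in ivals if r.label == "ZD-C1")
    zd_spec = DistSpec(zd.cum_mean, zd.cum_sd or 0.0, zd.cum_min, zd.cum_max)

    inter = []
    for row in ivals:
        if row.label == "ZD-C1":
            continue
        inter.append(
            DistSpec(row.step_mean, row.step_sd or 0.0, row.step_min, row.step_max)
        )
    sizes = [
        DistSpec(row.mean, row.sd or 0.0, row.min, row.max)
        for row in clutch_number_stats(records)
    ]
    counts = [len(r.clutches) for r in records]
    count_dist = {
        k: counts.count(k) / len(counts) for k in sorted(set(counts))
    }
    post = [
        float(r.death_day - r.last_clutch_day)
        for r in records
        if not r.censored and r.death_day is not None and r.clutches
    ]
    lifespans = [
        float(r.death_day)
        for r in records
        if not r.censored and r.death_day is not None
    ]
    return SimParams(
        label=label,
        zd_c1=zd_spec,
        inter_clutch=inter,
        clutch_size=sizes,
        clutch_count=count_dist,
        post_last_survival=_spec_from_values(post) if post else DistSpec(0.0, 0.0),
        lifespan=_spec_from_values(lifespans) if lifespans else DistSpec(0.0, 0.0),
    )


def estimate_params_from_cohort(
    log: CohortLog, label: str = "from_cohort"
) -> SimParams:
    """Moment estimates from an anonymous cohort log via round inference.

    Individual pairing is unknowable in a cohort, so identification runs
    through :func:`assign_rounds`: round-1 days give the zygote-to-first-
    clutch spec; the k -> k+1 interval mean is the difference of adjacent
    round day means with SD pooled (Bessel-weighted) from the two rounds'
    day spreads; clutch sizes come per round; clutch_count from the round
    clutch counts (quota attrition); post-last survival from deaths after
    the final clutch. Every choice is recorded in ``notes``.
    """
    assignment = assign_rounds(log)
    if assignment.n_clutches == 0:
        raise EstimationError("cohort log has no clutches")
    clutches = sorted(log.clutches, key=lambda c: c.day)
    rounds = round_summaries(assignment, log)
    by_round: dict[int, list[ClutchEvent]] = {}
    for c, lab in zip(clutches, assignment.labels):
        by_round.setdefault(lab, []).append(c)

    r1_days = [float(c.day) for c in by_round[1]]
    zd_spec = _spec_from_values(r1_days)

    inter = []
    for k in range(1, len(rounds)):
        a, b = rounds[k - 1], rounds[k]
        da = [float(c.day) for c in by_round[a.index]]
        db = [float(c.day) for c in by_round[b.index]]
        sa = float(np.std(da, ddof=1)) if len(da) >= 2 else 0.0
        sb = float(np.std(db, ddof=1)) if len(db) >= 2 else 0.0
        dof = max(len(da) - 1, 0) + max(len(db) - 1, 0)
        pooled = (
            math.sqrt(((len(da) - 1) * sa**2 + (len(db) - 1) * sb**2) / dof)
            if dof > 0
            else 0.0
        )
        inter.append(
            DistSpec(mean=b.day_mean - a.day_mean, sd=pooled, min=1.0, max=None)
        )
    sizes = [
        _spec_from_values([float(c.size) for c in by_round[r.index]]) for r in rounds
    ]
    count_dist = categorical_from_survival_counts(
        [r.n for r in rounds], rounds[0].quota
    )
    last_day = clutches[-1].day
    post = [float(d - last_day) for d in log.death_days if d >= last_day]
    lifespans = [float(d) for d in log.death_days]
    return SimParams(
        label=label,
        zd_c1=zd_spec,
        inter_clutch=inter,
        clutch_size=sizes,
        clutch_count=count_dist,
        post_last_survival=_spec_from_values(post) if post else DistSpec(0.0, 0.0),
        lifespan=_spec_from_values(lifespans) if lifespans else DistSpec(0.0, 0.0),
        notes={
            "identification": (
                "zd_c1 from round-1 days; inter-clutch mean = difference of "
                "adjacent round day means, SD pooled from both rounds' day "
                "spreads; clutch sizes per round; clutch_count from round "
                "clutch counts with N = round-1 quota; post-last survival "
                "from deaths on/after the final clutch day"
            ),
            "n_rounds": len(rounds),
        },
    )


def _draw_count(params: SimParams, rng: np.random.Generator) -> int:
    ks = sorted(params.clutch_count)
    ps = np.array([params.clutch_count[k] for k in ks], dtype=float)
    return int(ks[rng.choice(len(ks), p=ps / ps.sum())])


def simulate_individual(
    params: SimParams, rng: np.random.Generator, id: str = "sim"
) -> IndividualRecord:
    """Simulate one animal's full schedule.

    Draw order is fixed (count, first-clutch day, then per clutch interval
    and size, then survival), so a given (params, rng state) always yields
    the same record. Values are rounded to integer days/sizes; intervals
    are forced >= 1 day and sizes >= 1 embryo.
    """
    params.validate_reachable()  # fail fast before any draw
    m = _draw_count(params, rng)
    if m == 0:
        death = max(int(round(params.lifespan.sample(rng))), 0)
        return IndividualRecord(id=id, death_day=death, clutches=[])
    clutches = []
    day = max(int(round(params.zd_c1.sample(rng))), 0)
    for k in range(1, m + 1):
        if k > 1:
            day += max(int(round(params.inter_clutch[k - 2].sample(rng))), 1)
        size = max(int(round(params.clutch_size[k - 1].sample(rng))), 1)
        clutches.append(ClutchEvent(day=day, size=size, parent_id=id))
    death = day + max(int(round(params.post_last_survival.sample(rng))), 0)
    return IndividualRecord(id=id, death_day=death, clutches=clutches)


def _substream(seed: int, run: int, idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(run, idx)))


def simulate_records(
    params: SimParams, n: int, seed: int, run: int = 0
) -> list[IndividualRecord]:
    """n independent individuals with counter-derived substreams."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        simulate_individual(params, _substream(seed, run, i), id=f"sim{run}_{i:03d}")
        for i in range(n)
    ]


def simulate_cohort(
    params: SimParams,
    n: int,
    rng: Union[int, np.random.Generator],
    run: int = 0,
) -> CohortLog:
    """Simulate an anonymized cohort of n *independent* individuals.

    This is the no-interaction null model: individuals never coordinate,
    so any clustering in real cohorts beyond what these logs show needs a
    mechanism outside the model. Accepts a seed (preferred, gives
    counter-derived substreams) or a Generator (a base seed is drawn from
    it first).
    """
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(2**31))
    else:
        seed = int(rng)
    records = simulate_records(params, n, seed, run=run)
    log = build_pseudo_cohort(records)
    log.label = f"sim:{params.label}"
    return log


@dataclass(frozen=True)
class MetricSummary:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    ci95: tuple[float, float]


@dataclass
class ReplicateSummary:
    """Pooled per-metric summaries over all simulated individuals.

    Metric keys: ``zd_c1``, ``interval_k`` (transition k -> k+1),
    ``interval_all`` (every consecutive interval pooled), ``size_k``,
    ``clutch_count``, ``post_last_survival``, ``lifespan``, ``capacity``.
    """

    label: str
    runs: int
    n: int
    seed: int
    metrics: dict[str, MetricSummary]


def _summarize(values: Sequence[float]) -> MetricSummary:
    arr = np.asarray(values, dtype=float)
    n = arr.size
    m = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n >= 2 else 0.0
    if n >= 2 and sd > 0:
        half = float(_sps.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
    else:
        half = 0.0
    return MetricSummary(
        n=n, mean=m, sd=sd, min=float(arr.min()), max=float(arr.max()),
        ci95=(m - half, m + half),
    )


def run_replicates(
    params: SimParams, n: int, runs: int = 100, seed: int = 0
) -> ReplicateSummary:
    """Simulate ``runs`` cohorts of ``n`` individuals and pool the metrics.

    Fully reproducible from (params, n, runs, seed); identical inputs give
    identical summaries.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    pools: dict[str, list[float]] = {
        "zd_c1": [], "interval_all": [], "clutch_count": [],
        "post_last_survival": [], "lifespan": [], "capacity": [],
    }
    for run in range(runs):
        for rec in simulate_records(params, n, seed, run=run):
            m = len(rec.clutches)
            pools["clutch_count"].append(float(m))
            pools["capacity"].append(float(rec.total_embryos))
            pools["lifespan"].append(float(rec.death_day))
            if m == 0:
                continue
            pools["zd_c1"].append(float(rec.clutches[0].day))
            pools["post_last_survival"].append(
                float(rec.death_day - rec.clutches[-1].day)
            )
            for k in range(1, m):
                step = float(rec.clutches[k].day - rec.clutches[k - 1].day)
                pools["interval_all"].append(step)
                pools.setdefault(f"interval_{k}", []).append(step)
            for k, c in enumerate(rec.clutches, start=1):
                pools.setdefault(f"size_{k}", []).append(float(c.size))
    metrics = {name: _summarize(vals) for name, vals in pools.items() if vals}
    return ReplicateSummary(
        label=params.label, runs=runs, n=n, seed=seed, metrics=metrics
    )
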