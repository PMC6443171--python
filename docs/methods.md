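# Methods

## Data model and conventions

An individual's record is its birth (day 0 = deposition of the zygote it
developed from), an ordered list of clutch events (integer day, integer
embryo count ≥ 1), and an integer death day or a censored flag. A cohort
log is the anonymized group view: initial size n₀, the multiset of observed
death days, and unattributed clutch events in day order.

Observations are daily, so all times are whole days. An animal recorded
dead on day *d* was seen alive at that day's check, so it counts as present
on *d*: `alive(d) = n0 − #{deaths strictly before d}`. Ties (several
clutches on one day) keep input order; every sort in the package is stable,
so results are invariant to input row order.

## Life-history tables

Per-clutch-index statistics use the sample SD (n−1 denominator); a
singleton sample reports its bare value with SD absent rather than 0,
matching how such tables are conventionally printed. Two different interval
quantities are kept apart deliberately:

* **cumulative** — days from birth to clutch *k*, over animals possessing
  clutch *k*;
* **step** — the per-individual difference day₍ₖ₊₁₎ − dayₖ, over animals
  possessing *both* clutches.

The step mean is *not* the difference of cumulative means when the two
samples contain different animals, and only the per-individual pairing is
well-defined from raw records, so the step statistics are always computed
from pairs. Reproductive capacity is total embryos over a lifetime; its
table-based reconstruction `Σ_k S_k·mean_k / N` is exact when the table's
means are exact, and agrees with the record-based computation to rounding
(a conservation law the tests enforce).

## Round assignment for cohorts

Round *r* opens at the first unassigned clutch; its quota is the number of
animals alive at the opening day; the next quota clutches (in day order)
belong to round *r*. A trailing round that never fills its quota is kept
and flagged incomplete rather than discarded — a lone late clutch is still
evidence of a further reproductive episode. Per-round day and size means
carry Student-*t* confidence intervals (mean ± t₍n−1,0.975₎·sd/√n), omitted
for n < 2. The *t* interval is a choice, not an identity: the CI method
behind previously printed figure legends is not stated and their values
cannot be reproduced consistently from rounded table moments, so CIs here
are covered by closed-form method tests rather than by comparison to any
printed interval.

Two failure modes of the counting rule follow from its definition and are
treated as first-class, testable behaviour:

1. an animal present at a round's opening that dies (or fails to breed)
   before laying leaves the quota one short, pulling the earliest
   next-round clutch back into the round;
2. when the temporal spread of laying approaches the gap between rounds,
   boundary clutches swap rounds.

The synthetic generator produces datasets with ground-truth labels so both
modes are measured, not assumed. On the pseudo-cohort built by pooling the
16 synthetic isolated records, the rule infers 6 rounds against 8 true
clutch ranks with ≈50% of clutches mislabelled — pooled unsynchronized
individuals are exactly the regime where counting-by-quota breaks down.

## The simulator and its sampling law

Each animal draws, in fixed order: clutch count *m* from a categorical
distribution; day₁ from the ZD-C1 distribution; then for each transition an
interval (floored at 1 day) and for each clutch a size (floored at 1
embryo); finally death = last clutch day + post-last survival (never-laying
animals draw a lifespan instead). Draws round to integers. Individuals are
independent by construction — the model deliberately contains no
mate-finding or coordination mechanism, because it is the null against
which cohort synchrony is judged. Under it the SD of the *k*-th clutch day
across animals grows with *k* (variance of summed independent intervals),
so simulated cohorts cannot stay clustered after round 1.

Every marginal is a **normal truncated to [min, max]**, the minimal law
consistent with reporting mean ± SD and (min, max). Two numerical choices:

* **Moment calibration.** The reported mean/SD describe the bounded data,
  i.e. they are moments of the truncated distribution. The parent (μ, σ)
  are therefore solved (least squares on `scipy.stats.truncnorm` moments,
  mean residual weighted 50×) so that the truncated moments match the
  targets. Truncating N(mean, sd) naively would shift the mean by up to
  ~2 days for asymmetric bounds. When the target SD exceeds what any
  truncated normal on the support can reach (the uniform limit
  (max−min)/√12 — e.g. SD 25.8 on a 60-day support), the calibrated SD
  saturates below target while the mean still matches; the affected specs
  are small-sample rows where a sample SD can legitimately exceed the
  family's supremum.
* **Inverse-CDF sampling.** Calibrated parents can sit far outside the
  bounds, where rejection sampling would accept <1% of draws and the
  parent CDF at the bounds loses floating-point precision. Draws therefore
  invert the truncated CDF via `ndtri`, switching to survival-function
  space when the support lies in the parent's upper tail. The law is
  identical to rejection from the same parent and deterministic under the
  supplied generator.

Reproducibility: one seed per replicate batch; each (run, individual) gets
a counter-derived `SeedSequence` substream, so enlarging n or runs never
reshuffles other individuals' draws.

## Parameter sets

Five presets transcribe the published summary blocks (isolated
*H. robusta* N=16; the 48-animal *H. robusta* cohort; isolated
*H. octatestisaca* N=5; *H. austinensis* cohorts of 23 and 60). Choices
where the tables underdetermine the model:

* **Clutch-count distribution** from the per-index sample sizes S₁..S_K:
  P(m=k) ∝ max(S_k − S_{k+1}, 0). Negative differences (a missed first
  clutch makes S₁ < S₂ in the isolated *H. robusta* block) clip to zero,
  and P(0) absorbs the max(N − max_k S_k, 0) individuals left unaccounted.
* **Inter-clutch interval SDs** are not printed — the SD/min/max columns
  beside the printed step means are cumulative-day statistics (e.g. the
  C1-C2 row's (72, 93) brackets the day of C2, not a 28-day step). The
  later clutch's cumulative SD stands in as the step spread, with a 1-day
  floor and no upper bound; this is an upper proxy, and it preserves the
  qualitative property that matters (interval variance large enough to
  destroy synchrony).
* **Post-last survival and lifespan** are only anchored loosely by the
  source material (mean lifespans of 229 and 246 days for the two isolated
  groups; a cohort whose last survivor died 34 days after the final
  clutch; another whose survivors lived >100 reproduction-free days). The
  preset values are derived from those anchors once and recorded in each
  preset file's notes; they affect no headline quantity (first-clutch
  timing and intervals never touch them).

Cohort-based estimation (`estimate_params_from_cohort`) identifies what it
can through round inference: ZD-C1 from round-1 days; interval *k* mean as
the difference of adjacent round day means with SD pooled (Bessel-weighted)
from both rounds' spreads; sizes per round; clutch counts from round-count
attrition; post-last survival from deaths on/after the final clutch day.
These are coarse identifications — individual pairing is unknowable in a
cohort — and each is recorded in the emitted parameter file.

## What the synthetic data does and does not show

The generator reproduces: per-index clutch-size and interval moments of
the table blocks (verified empirically at n = 5000 within the truncation
saturation noted above), the categorical clutch-count distribution,
post-last-clutch survival, anonymization, and exact ground-truth labels.
It does not reproduce: any coordination between animals (real cohorts are
*more* synchronized than the null — that discrepancy is the scientific
point, and a generator that faked it would beg the question); seasonal or
diet effects; estimated-vs-observed laying dates (records carry an
`estimated` flag but no correction model); or the actual unpublished
per-animal values. Passing tests therefore certify the pipeline's
correctness on schedule-structured data, not any new biological claim.

## Problem sizes and runtime

Replicate summaries use 100 runs at the experiments' cohort sizes (16, 48,
5) — about 7,000 simulated animals per summary, giving standard errors of
~0.15–0.7 days on pooled timing means, well inside the comparisons made
with them. The fidelity check uses one 5,000-animal draw. The full test
suite runs in well under a minute of simulation time.

## Known limitations

* The truncated-normal family cannot represent heavy-tailed or strongly
  skewed interval data; with only printed moments available, nothing
  richer is identifiable. The sampling law is isolated behind
  `DistSpec.sample` and swappable.
* The round-counting rule is implemented exactly as defined, including its
  failure modes; no clustering-based alternative (e.g. k-means on
  deposition days) is provided, since the rule itself is the object under
  study.
* Cohort interval SDs pool adjacent rounds' day spreads, which double-counts
  shared between-animal variation; they are upper bounds on the true step
  SD.
* `capacity_from_stats` inherits the printed tables' rounding; totals
  reconstructed from one-decimal means can differ from raw totals by a few
  embryos.
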