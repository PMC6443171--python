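"""Round assignment: hand-executed examples, an independent oracle over
randomly drawn small logs, summaries, binning and series."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clutchwork.cohort_inference import (
    assign_rounds,
    bin_depositions,
    build_pseudo_cohort,
    cohort_series,
    round_summaries,
)
from clutchwork.records_io import ClutchEvent, CohortLog
from conftest import record


def log_of(n0, deaths, day_size_pairs):
    return CohortLog(
        n0=n0,
        death_days=sorted(deaths),
        clutches=[ClutchEvent(day=d, size=s) for d, s in day_size_pairs],
    )


class TestAssignRounds:
    def test_no_deaths_two_full_rounds(self):
        log = log_of(3, [], [(50, 1), (52, 1), (55, 1), (80, 1), (81, 1), (83, 1)])
        assert assign_rounds(log).labels == [1, 1, 1, 2, 2, 2]

    def test_death_shrinks_later_quota(self):
        log = log_of(3, [70], [(50, 1), (52, 1), (55, 1), (80, 1), (81, 1), (90, 1)])
        a = assign_rounds(log)
        assert a.labels == [1, 1, 1, 2, 2, 3]
        assert a.quotas == [3, 2, 2]  # round 3 opened with quota 2, got 1

    def test_single_animal_one_clutch_per_round(self):
        log = log_of(1, [], [(40, 1), (70, 1), (95, 1)])
        assert assign_rounds(log).labels == [1, 2, 3]

    def test_empty_log(self):
        a = assign_rounds(log_of(2, [], []))
        assert a.labels == [] and a.n_rounds == 0

    def test_death_on_opening_day_still_counts_present(self):
        # the animal observed dead on day 50 was alive at that day's check
        log = log_of(2, [50], [(50, 1), (52, 1), (60, 1)])
        assert assign_rounds(log).quotas[0] == 2

    def test_input_order_invariance_with_same_day_ties(self):
        events = [(50, 1), (50, 2), (52, 3), (80, 4), (80, 5), (81, 6)]
        base = assign_rounds(log_of(3, [], events))
        # reversing rows of different days must not change labels per (day,size)
        resorted = sorted(events, key=lambda e: e[0])
        again = assign_rounds(log_of(3, [], resorted))
        assert base.labels == again.labels


# Independent transcription of the counting rule, consuming a literal queue.
def oracle_labels(n0, deaths, days):
    labels, queue, r = [], list(days), 0
    while queue:
        r += 1
        present = n0 - sum(1 for d in deaths if d < queue[0])
        for _ in range(max(present, 1)):
            if not queue:
                break
            queue.pop(0)
            labels.append(r)
    return labels


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    n0=st.integers(1, 4),
    deaths=st.lists(st.integers(0, 30), max_size=4),
    days=st.lists(st.integers(0, 30), max_size=8),
)
def test_assignment_matches_oracle_on_small_logs(n0, deaths, days):
    deaths = deaths[:n0]
    days = sorted(days)
    log = log_of(n0, deaths, [(d, 1) for d in days])
    a = assign_rounds(log)
    assert a.labels == oracle_labels(n0, deaths, days)
    # quota law: every round except possibly the last is exactly full
    counts = [a.labels.count(r) for r in range(1, a.n_rounds + 1)]
    for c, q in zip(counts[:-1], a.quotas[:-1]):
        assert c == q
    if counts:
        assert counts[-1] <= a.quotas[-1]


class TestRoundSummaries:
    def test_two_clutch_round_t_interval(self):
        log = log_of(2, [], [(100, 10), (102, 14)])
        (s,) = round_summaries(assign_rounds(log), log)
        assert s.day_mean == 101 and s.size_mean == 12
        # n=2: half-width = t_{1,0.975} * sd/sqrt(2) = 12.7062 * 1
        assert s.day_ci[1] - s.day_mean == pytest.approx(12.7062, abs=1e-3)

    def test_singleton_round_has_no_ci(self):
        log = log_of(1, [], [(40, 9)])
        (s,) = round_summaries(assign_rounds(log), log)
        assert s.day_ci is None and s.size_ci is None and s.n == 1

    def test_identical_values_zero_width_ci(self):
        log = log_of(3, [], [(60, 8), (60, 8), (60, 8)])
        (s,) = round_summaries(assign_rounds(log), log)
        assert s.day_ci == (60, 60) and s.size_ci == (8, 8)

    def test_partial_final_round_flagged(self, simple_cohort):
        rounds = round_summaries(assign_rounds(simple_cohort), simple_cohort)
        assert [r.complete for r in rounds] == [True, True, False]

    def test_mismatched_log_rejected(self, simple_cohort):
        a = assign_rounds(simple_cohort)
        with pytest.raises(ValueError, match="assignment covers"):
            round_summaries(a, log_of(1, [], [(5, 1)]))


class TestPseudoCohort:
    def test_conserves_totals(self, pair_records):
        log = build_pseudo_cohort(pair_records)
        assert log.n0 == 2
        assert len(log.clutches) == 3
        assert log.total_embryos == 60
        assert log.clutches[0].parent_id is None

    def test_day_sorted_with_stable_ties(self):
        recs = [record("A", 99, [(50, 1), (60, 3)]), record("B", 99, [(50, 2)])]
        log = build_pseudo_cohort(recs)
        assert [(c.day, c.size) for c in log.clutches] == [(50, 1), (50, 2), (60, 3)]

    def test_censored_records_contribute_no_death(self):
        recs = [record("A", None, [(50, 1)], censored=True), record("B", 80, [])]
        log = build_pseudo_cohort(recs)
        assert log.death_days == [80] and log.n0 == 2


class TestBinning:
    def test_half_open_bins(self):
        log = log_of(5, [], [(0, 1), (4, 1), (5, 1), (9, 1), (10, 1)])
        h = bin_depositions(log, width=5)
        assert h.counts == [2, 2, 1] and h.starts == [0, 5, 10]

    def test_empty_log_empty_histogram(self):
        h = bin_depositions(log_of(2, [], []))
        assert h.counts == [] and h.starts == []

    def test_width_one_gives_daily_tallies(self):
        log = log_of(3, [], [(2, 1), (2, 1), (4, 1)])
        h = bin_depositions(log, width=1)
        assert h.counts == [0, 0, 2, 0, 1]

    def test_bad_width_rejected(self, simple_cohort):
        with pytest.raises(ValueError):
            bin_depositions(simple_cohort, width=0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        days=st.lists(st.integers(0, 200), min_size=1, max_size=30),
        width=st.integers(1, 14),
    )
    def test_counts_always_sum_to_clutches(self, days, width):
        log = log_of(5, [], [(d, 1) for d in sorted(days)])
        assert sum(bin_depositions(log, width).counts) == len(days)


class TestCohortSeries:
    def test_death_day_convention(self):
        s = cohort_series(log_of(3, [70], []))
        assert s.alive[70] == 3 and s.alive[69] == 3
        assert len(s.alive) == 71  # horizon is the last event

    def test_cumulative_embryos(self):
        s = cohort_series(log_of(3, [], [(50, 10), (80, 12)]))
        assert s.cum_embryos[49] == 0
        assert s.cum_embryos[50] == 10 and s.cum_embryos[79] == 10
        assert s.cum_embryos[80] == 22

    def test_empty_log_flat_series(self):
        s = cohort_series(log_of(2, [], []))
        assert s.alive == [2] and s.cum_clutches == [0]

    def test_monotonicity(self, simple_cohort):
        s = cohort_series(simple_cohort)
        assert all(b <= a for a, b in zip(s.alive, s.alive[1:]))
        assert all(b >= a for a, b in zip(s.cum_clutches, s.cum_clutches[1:]))
        assert all(b >= a for a, b in zip(s.cum_embryos, s.cum_embryos[1:]))
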