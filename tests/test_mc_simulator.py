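"""Simulator: determinism, truncation correctness, moment recovery, and
the estimate -> simulate -> estimate fixed point."""

import dataclasses
import math

import numpy as np
import pytest

from clutchwork.mc_simulator import (
    DistSpec,
    EstimationError,
    SimParams,
    categorical_from_survival_counts,
    estimate_params_from_cohort,
    estimate_params_from_individuals,
    run_replicates,
    simulate_cohort,
    simulate_individual,
    simulate_records,
)
from clutchwork.cohort_inference import assign_rounds, build_pseudo_cohort
from conftest import record


class TestDistSpec:
    def test_mean_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside bounds"):
            DistSpec(mean=5, sd=1, min=10, max=20)

    def test_point_mass(self):
        rng = np.random.default_rng(0)
        assert DistSpec(13, 0, 13, 13).sample(rng) == 13
        assert DistSpec(56, 0).sample(rng) == 56

    @pytest.mark.parametrize(
        "spec",
        [
            DistSpec(56.3, 8.7, 37, 68),
            DistSpec(24.0, 10.0, 11, 65),
            DistSpec(28, 7.7, 1, None),
            DistSpec(21, 37.7, 1, None),
        ],
        ids=lambda s: f"m{s.mean}",
    )
    def test_draws_respect_bounds(self, spec):
        rng = np.random.default_rng(42)
        draws = [spec.sample(rng) for _ in range(2000)]
        if spec.min is not None:
            assert min(draws) >= spec.min
        if spec.max is not None:
            assert max(draws) <= spec.max

    def test_moment_recovery_first_clutch_timing(self):
        """1600 draws of the (56.3, 8.7, 37, 68) generation-time spec land
        within 3 standard errors of the target mean."""
        spec = DistSpec(56.3, 8.7, 37, 68)
        rng = np.random.default_rng(7)
        draws = np.array([spec.sample(rng) for _ in range(1600)])
        assert abs(draws.mean() - 56.3) < 3 * 8.7 / math.sqrt(1600)

    def test_json_round_trip(self):
        spec = DistSpec(28, 7.7, 1, None)
        assert DistSpec.from_json(spec.to_json()) == spec


class TestCategoricalFromS:
    def test_monotone_counts(self):
        # 48, 34, 28, 26, 13 -> exactly-k counts 14, 6, 2, 13, 13
        dist = categorical_from_survival_counts([48, 34, 28, 26, 13], 48)
        assert dist == pytest.approx(
            {1: 14 / 48, 2: 6 / 48, 3: 2 / 48, 4: 13 / 48, 5: 13 / 48}
        )

    def test_non_monotone_counts_clipped_and_zero_class(self):
        # S1 < S2 (a missed first clutch); negative differences clip to 0
        # and the unaccounted individuals go to the zero class
        dist = categorical_from_survival_counts([10, 14, 14, 11, 11, 9, 6, 1], 16)
        assert sum(dist.values()) == pytest.approx(1)
        assert dist[0] == pytest.approx(2 / 16)
        assert dist[7] == pytest.approx(5 / 16)
        assert 1 not in dist and 2 not in dist


class TestSimulateIndividual:
    def test_point_mass_schedule(self, point_mass_params):
        rec = simulate_individual(point_mass_params, np.random.default_rng(0))
        assert [(c.day, c.size) for c in rec.clutches] == [
            (56, 20), (84, 50), (112, 70)
        ]
        assert rec.death_day == 142

    def test_same_seed_same_record(self, spread_params):
        a = simulate_individual(spread_params, np.random.default_rng(5))
        b = simulate_individual(spread_params, np.random.default_rng(5))
        assert a.clutches == b.clutches and a.death_day == b.death_day

    def test_unreachable_count_fails_fast(self, point_mass_params):
        # rejected at construction, before any draw could happen
        with pytest.raises(ValueError, match="clutch count 4"):
            dataclasses.replace(point_mass_params, clutch_count={4: 1.0})

    def test_zero_count_uses_lifespan(self, point_mass_params):
        bare = dataclasses.replace(point_mass_params, clutch_count={0: 1.0})
        rec = simulate_individual(bare, np.random.default_rng(0))
        assert rec.clutches == [] and rec.death_day == 200


class TestSimulateCohort:
    def test_point_mass_cohort_recovers_rounds_exactly(self, point_mass_params):
        log = simulate_cohort(point_mass_params, n=16, rng=3)
        a = assign_rounds(log)
        assert a.n_rounds == 3 and a.labels == [1] * 16 + [2] * 16 + [3] * 16

    def test_embryo_totals_conserved(self, spread_params):
        recs = simulate_records(spread_params, 20, seed=11)
        log = build_pseudo_cohort(recs)
        assert log.total_embryos == sum(r.total_embryos for r in recs)

    def test_counter_substreams_are_stable_in_n(self, spread_params):
        small = simulate_records(spread_params, 5, seed=9)
        large = simulate_records(spread_params, 9, seed=9)
        assert [r.clutches for r in small] == [r.clutches for r in large[:5]]

    def test_variance_accumulates_across_rounds(self, spread_params):
        """Independent interval draws smear later rounds: the spread of the
        k-th clutch day across animals grows with k, which is exactly why
        this null model cannot hold a cohort in tight synchrony."""
        recs = simulate_records(spread_params, 400, seed=21)
        sds = [
            np.std([r.clutches[k].day for r in recs], ddof=1) for k in range(3)
        ]
        assert sds[0] < sds[1] < sds[2]


class TestEstimators:
    def test_individuals_example(self, pair_records):
        params = estimate_params_from_individuals(pair_records)
        zd = params.zd_c1
        assert zd.mean == pytest.approx(55)
        assert zd.sd == pytest.approx(math.sqrt(50))
        assert (zd.min, zd.max) == (50, 60)
        assert params.clutch_count == {1: 0.5, 2: 0.5}

    def test_fixed_point_for_point_mass(self, point_mass_params):
        recs = simulate_records(point_mass_params, 4, seed=0)
        back = estimate_params_from_individuals(recs)
        assert back.zd_c1.mean == 56 and back.zd_c1.sd == 0
        assert [d.mean for d in back.inter_clutch] == [28, 28]
        assert [d.mean for d in back.clutch_size] == [20, 50, 70]
        assert back.clutch_count == {3: 1.0}
        assert back.post_last_survival.mean == 30

    def test_cohort_estimation_recovers_separated_round_means(self, spread_params):
        log = simulate_cohort(spread_params, n=40, rng=2)
        params = estimate_params_from_cohort(log)
        # truth: zd 56 +/- 2; rounds separated by 40 day steps
        assert abs(params.zd_c1.mean - 56) < 3 * 2 / math.sqrt(40) + 0.5
        assert len(params.inter_clutch) == 2
        for spec in params.inter_clutch:
            assert abs(spec.mean - 40) < 2.0

    def test_cohort_estimation_consistent_with_individuals(self, point_mass_params):
        recs = simulate_records(point_mass_params, 6, seed=1)
        from_ind = estimate_params_from_individuals(recs)
        from_coh = estimate_params_from_cohort(build_pseudo_cohort(recs))
        assert from_coh.zd_c1.mean == pytest.approx(from_ind.zd_c1.mean)
        assert [d.mean for d in from_coh.inter_clutch] == pytest.approx(
            [d.mean for d in from_ind.inter_clutch]
        )

    def test_single_round_cohort_lacks_interval_specs(self):
        from clutchwork.records_io import ClutchEvent, CohortLog

        log = CohortLog(
            n0=2, death_days=[],
            clutches=[ClutchEvent(day=50, size=5), ClutchEvent(day=52, size=6)],
        )
        params = estimate_params_from_cohort(log)
        assert params.inter_clutch == []
        with pytest.raises(ValueError, match="clutch count"):
            dataclasses.replace(params, clutch_count={2: 1.0})

    def test_empty_cohort_estimation_fails(self):
        from clutchwork.records_io import CohortLog

        with pytest.raises(EstimationError):
            estimate_params_from_cohort(CohortLog(n0=3))


class TestRunReplicates:
    def test_single_point_mass_run(self, point_mass_params):
        s = run_replicates(point_mass_params, n=1, runs=1, seed=0)
        zd = s.metrics["zd_c1"]
        assert (zd.mean, zd.sd, zd.ci95) == (56, 0, (56, 56))
        assert s.metrics["capacity"].mean == 140
        assert s.metrics["interval_all"].mean == 28

    def test_reproducible_across_calls(self, spread_params):
        a = run_replicates(spread_params, n=8, runs=3, seed=4)
        b = run_replicates(spread_params, n=8, runs=3, seed=4)
        assert a.metrics == b.metrics

    def test_metric_invariants(self, spread_params):
        s = run_replicates(spread_params, n=8, runs=5, seed=4)
        for m in s.metrics.values():
            assert m.min <= m.mean <= m.max
            assert m.ci95[0] <= m.mean <= m.ci95[1]
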