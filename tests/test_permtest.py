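"""Median-distance permutation tests and the Monte-Carlo p-value machinery."""

import dataclasses

import numpy as np
import pytest

from batconnectome.distances import DistanceMatrix
from batconnectome.errors import InputError
from batconnectome.permtest import (
    NullPool,
    build_null_pool,
    clopper_pearson,
    cross_group_closeness_test,
    empirical_p,
    sample_null_median,
    sample_null_medians,
    within_group_closeness_test,
)
from batconnectome.synthetic import null_distance_spec, simulate_distance_matrix


class TestClopperPearson:
    def test_zero_exceedance_closed_form(self):
        # upper bound for 0/n is 1 - (alpha/2)^(1/n)
        for n in (10_000, 1_000_000):
            lo, hi = clopper_pearson(0, n)
            assert lo == 0.0
            assert hi == pytest.approx(1 - 0.025 ** (1 / n), rel=1e-9)
        assert clopper_pearson(0, 1_000_000)[1] == pytest.approx(3.69e-6, rel=0.01)

    def test_interval_brackets_the_proportion(self):
        for k, n in [(1, 20), (5, 100), (99, 100)]:
            lo, hi = clopper_pearson(k, n)
            assert lo <= k / n <= hi


class TestEmpiricalP:
    def test_zero_exceedance_reporting(self):
        null = np.full(10_000, 10.0)
        res = empirical_p(4.72, null, "le")
        assert res.n_extreme == 0
        assert res.p_raw == 0.0
        assert res.p_adj == pytest.approx(1 / 10_001)
        assert res.ci95[0] == 0.0
        assert res.p_report == "p < 0.0001"

    def test_all_ties_are_extreme(self):
        null = np.full(1000, 3.0)
        assert empirical_p(3.0, null, "le").p_raw == 1.0
        assert empirical_p(3.0, null, "ge").p_raw == 1.0

    def test_monotone_in_observed_for_le_tail(self):
        rng = np.random.default_rng(5)
        null = rng.uniform(0, 1, 5000)
        ps = [empirical_p(obs, null, "le").p_raw for obs in np.linspace(0, 1, 17)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_adjusted_p_has_floor(self):
        res = empirical_p(-1.0, np.arange(1, 100, dtype=float), "le")
        assert res.p_adj == pytest.approx(1 / 100)
        assert res.p_raw <= res.p_adj

    def test_empty_stream_rejected(self):
        with pytest.raises(InputError):
            empirical_p(1.0, [], "le")


class TestNullPool:
    def test_pool_size_is_product_of_set_sizes(self, asym5):
        pool = build_null_pool(asym5, ["A", "B"], ["C", "D", "E"])
        assert pool.size == 6
        both = build_null_pool(asym5, ["A", "B"], ["C", "D", "E"], both_directions=True)
        assert both.size == 12

    def test_singleton_pool(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 5.0], [7.0, 0.0]]))
        pool = build_null_pool(dm, ["a"], ["b"])
        assert list(pool.values) == [5.0]

    def test_overlap_rejected(self, asym5):
        with pytest.raises(InputError):
            build_null_pool(asym5, ["A", "B"], ["B", "C"])


class TestSampling:
    def test_constant_pool_returns_constant(self):
        pool = NullPool(np.full(50, 4.2))
        rng = np.random.default_rng(0)
        assert sample_null_median(pool, 17, rng) == 4.2

    def test_exhaustive_draw_is_the_pool_median(self):
        pool = NullPool(np.array([1.0, 2.0, 3.0, 4.0]))
        rng = np.random.default_rng(0)
        assert all(sample_null_median(pool, 4, rng) == 2.5 for _ in range(10))

    def test_singleton_draws_average_to_pool_mean(self):
        pool = NullPool(np.array([0.0, 10.0]))
        draws = sample_null_medians(pool, 1, 4000, np.random.default_rng(1))
        assert np.mean(draws) == pytest.approx(5.0, abs=0.35)  # ~4.4 MC sigma

    def test_without_replacement_requires_room(self):
        pool = NullPool(np.arange(1.0, 5.0))
        with pytest.raises(InputError):
            sample_null_medians(pool, 5, 10, np.random.default_rng(0))
        # with replacement the same request is fine
        draws = sample_null_medians(pool, 5, 10, np.random.default_rng(0), replace=True)
        assert draws.shape == (10,)


class TestClosenessTests:
    @pytest.fixture()
    def planted(self):
        spec_dm = simulate_distance_matrix
        from batconnectome.synthetic import DistanceSimSpec

        spec = DistanceSimSpec(n_genes=150, module_size=12, seed=11)
        dm, module = spec_dm(spec)
        return spec, dm, module

    def test_seed_determinism_and_seed_sensitivity(self, planted):
        spec, dm, module = planted
        complement = set(dm.genes) - module - {spec.core}
        a = within_group_closeness_test(dm, module, complement, 500, seed=7)
        b = within_group_closeness_test(dm, module, complement, 500, seed=7)
        assert dataclasses.asdict(a) == dataclasses.asdict(b)
        c = within_group_closeness_test(dm, module, complement, 500, seed=8)
        assert c.observed == a.observed
        assert c.set_sizes == a.set_sizes

    def test_planted_module_is_detected(self, planted):
        spec, dm, module = planted
        complement = set(dm.genes) - module - {spec.core}
        res = within_group_closeness_test(dm, module, complement, 2000, seed=1)
        assert res.n_extreme == 0
        assert res.observed < np.median(dm.values[dm.values > 0])

    def test_single_candidate_single_known(self):
        v = np.array([[0.0, 2.0, 8.0], [3.0, 0.0, 9.0], [7.0, 6.0, 0.0]])
        dm = DistanceMatrix(("cand", "known", "out"), v)
        res = cross_group_closeness_test(dm, ["cand"], ["known"], ["out"], 100, seed=0)
        assert res.observed == 2.0  # the one cand->known distance

    def test_disjointness_enforced(self, asym5):
        with pytest.raises(InputError):
            cross_group_closeness_test(asym5, ["A"], ["A", "B"], ["C"], 10, 0)

    def test_group_of_one_rejected(self, asym5):
        with pytest.raises(InputError):
            within_group_closeness_test(asym5, ["A"], ["B", "C"], 10, 0)


class TestCrossCalibration:
    def test_type_i_error_under_exchangeable_null(self):
        """Candidates drawn from the same background as the outside pool give
        a calibrated cross-test: p_adj <= 0.05 in 3-8% of 500 replicates."""
        rng_seeds = np.random.SeedSequence(20).generate_state(1000) & 0x7FFFFFFF
        hits = 0
        n_rep = 500
        for i in range(n_rep):
            spec = null_distance_spec(n_genes=120, module_size=1, seed=int(rng_seeds[i]))
            dm, _ = simulate_distance_matrix(spec)
            genes = sorted(set(dm.genes) - {spec.core})
            cand, known, outside = genes[:8], genes[8:16], genes[16:]
            res = cross_group_closeness_test(
                dm, cand, known, outside, 1000, seed=int(rng_seeds[500 + i])
            )
            hits += res.p_adj <= 0.05
        assert 0.03 <= hits / n_rep <= 0.08
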