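"""Monte Carlo overlap null: sampling, p-values and small-instance oracles."""

import itertools
import math
from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from degmeta.overlap_null import (
    SimulationConfig,
    compare_sampling_modes,
    empirical_pvalue,
    overlap_total_from_lists,
    sample_gene_lists,
    simulate_null,
)


def exact_overlap_distribution(n_universe: int, list_sizes) -> dict[int, float]:
    """Exhaustive distribution of the >=2-list overlap under uniform sampling.

    Enumerates every combination of subsets (all equally likely under
    uniform sampling without replacement) — tractable only for tiny
    universes, which is exactly its role as an independent oracle.
    """
    universe = range(n_universe)
    dist: Counter = Counter()
    total = 0
    for combo in itertools.product(*(itertools.combinations(universe, s) for s in list_sizes)):
        counts = Counter(g for subset in combo for g in subset)
        dist[sum(1 for c in counts.values() if c >= 2)] += 1
        total += 1
    return {k: v / total for k, v in dist.items()}


def exact_tail(n_universe, list_sizes, x) -> float:
    dist = exact_overlap_distribution(n_universe, list_sizes)
    return sum(p for k, p in dist.items() if k >= x)


def make_cfg(**kw):
    base = dict(universe=list(range(6)), list_sizes=[2, 2], iterations=100,
                sampling="uniform", seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestSampling:
    def test_exhaustive_list_is_whole_universe(self):
        cfg = make_cfg(universe=["a", "b", "c"], list_sizes=[3])
        assert sample_gene_lists(cfg) == [{"a", "b", "c"}]

    def test_same_seed_reproduces_lists(self):
        cfg = make_cfg(list_sizes=[3, 2], seed=77)
        assert sample_gene_lists(cfg) == sample_gene_lists(cfg)

    def test_dominant_weight_is_almost_always_drawn(self):
        w = np.array([1e6, 1.0, 1.0])
        cfg = make_cfg(universe=[0, 1, 2], list_sizes=[1], sampling="weighted",
                       weights=w, iterations=10_000, seed=3)
        null = simulate_null(cfg)  # exercises the same sampler
        rng = np.random.default_rng(5)
        hits = sum(0 in sample_gene_lists(cfg, rng)[0] for _ in range(2_000))
        assert hits / 2_000 >= 0.99
        assert null.iterations == 10_000

    def test_list_size_exceeding_universe_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            make_cfg(list_sizes=[7]).validate()

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            make_cfg(sampling="weighted", weights=[1.0, 0.0, 1, 1, 1, 1]).validate()

    def test_weighted_size1_matches_plackett_luce_exactly(self):
        # With one draw the inclusion probability is w_i / sum(w).
        w = np.array([4.0, 2.0, 1.0, 1.0])
        cfg = make_cfg(universe=[0, 1, 2, 3], list_sizes=[1], sampling="weighted",
                       weights=w, iterations=20_000, seed=9)
        rng = np.random.default_rng(11)
        draws = Counter(next(iter(sample_gene_lists(cfg, rng)[0])) for _ in range(8_000))
        for g in range(4):
            p = w[g] / w.sum()
            se = math.sqrt(p * (1 - p) / 8_000)
            assert abs(draws[g] / 8_000 - p) < 4 * se


class TestSimulateNull:
    def test_two_lists_of_two_from_four_matches_enumeration(self):
        # P(no overlap) = C(2,2)/C(4,2) = 1/6, so P(overlap >= 1) = 5/6.
        cfg = make_cfg(universe=list(range(4)), list_sizes=[2, 2],
                       iterations=10_000, seed=21)
        null = simulate_null(cfg)
        p_hat = float((null.per_iteration_total_multi >= 1).mean())
        p_exact = exact_tail(4, [2, 2], 1)
        assert p_exact == pytest.approx(5 / 6)
        se = math.sqrt(p_exact * (1 - p_exact) / cfg.iterations)
        assert abs(p_hat - p_exact) < 3 * se

    def test_full_size_lists_overlap_completely(self):
        cfg = make_cfg(universe=list(range(5)), list_sizes=[5, 5], iterations=50)
        null = simulate_null(cfg)
        assert np.all(null.per_iteration_total_multi == 5)

    def test_single_list_never_overlaps(self):
        null = simulate_null(make_cfg(list_sizes=[3], iterations=50))
        assert np.all(null.per_iteration_total_multi == 0)

    def test_reproducible_bit_for_bit(self):
        cfg = make_cfg(universe=list(range(40)), list_sizes=[10, 8, 12],
                       iterations=500, seed=13)
        a, b = simulate_null(cfg), simulate_null(cfg)
        assert np.array_equal(a.per_iteration_total_multi, b.per_iteration_total_multi)
        for k in a.per_iteration_counts_by_level:
            assert np.array_equal(a.per_iteration_counts_by_level[k],
                                  b.per_iteration_counts_by_level[k])

    def test_levels_sum_to_totals(self):
        cfg = make_cfg(universe=list(range(30)), list_sizes=[8, 9, 10], iterations=300)
        null = simulate_null(cfg)
        multi = sum(null.per_iteration_counts_by_level[k] for k in (2, 3))
        assert np.array_equal(multi, null.per_iteration_total_multi)

    def test_enlarging_a_list_never_lowers_mean_overlap(self):
        means = []
        for size in (4, 8, 12, 16):
            cfg = make_cfg(universe=list(range(40)), list_sizes=[10, size],
                           iterations=2_000, seed=99)
            means.append(simulate_null(cfg).mean_total)
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))

    def test_directed_null_is_not_larger_than_identity_null(self):
        cfg = make_cfg(universe=list(range(30)), list_sizes=[10, 10, 10],
                       iterations=2_000, seed=5)
        identity = simulate_null(cfg)
        directed = simulate_null(replace(cfg, simulate_directions=[0.5, 0.5, 0.5]))
        assert directed.mean_total <= identity.mean_total


class TestEmpiricalPValue:
    def test_observed_zero_gives_p_one(self):
        null = simulate_null(make_cfg(iterations=200))
        res = empirical_pvalue(null, 0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.p_is_bound

    def test_direct_count_example(self):
        null = simulate_null(make_cfg(iterations=3))
        null.per_iteration_total_multi = np.array([1, 2, 3])
        res = empirical_pvalue(null, 2)
        assert res.exceedances == 2
        assert res.p_value == pytest.approx(3 / 4)

    def test_unreached_observation_renders_as_bound(self):
        null = simulate_null(make_cfg(universe=list(range(50)), list_sizes=[2, 2],
                                      iterations=10_000, seed=8))
        res = empirical_pvalue(null, 3)  # impossible: max overlap is 2
        assert res.p_is_bound
        assert res.p_value == pytest.approx(1 / 10_001)
        assert res.format_p() == "< 0.0001"


class TestSamplingModes:
    def test_heterogeneous_weights_raise_mean_overlap(self):
        rng = np.random.default_rng(17)
        weights = rng.lognormal(mean=0.0, sigma=1.5, size=200)
        cfg = SimulationConfig(universe=list(range(200)), list_sizes=[20, 25, 30, 20],
                               iterations=10_000, sampling="weighted", seed=23,
                               weights=weights)
        cmp = compare_sampling_modes(cfg)
        assert cmp.mean_difference > 0

    def test_equal_weights_reduce_to_uniform(self):
        cfg = SimulationConfig(universe=list(range(60)), list_sizes=[15, 15],
                               iterations=5_000, sampling="weighted", seed=29,
                               weights=np.ones(60))
        cmp = compare_sampling_modes(cfg)
        se = math.sqrt(cmp.weighted.sd_total ** 2 / 5_000 + cmp.uniform.sd_total ** 2 / 5_000)
        assert abs(cmp.mean_difference) < 3 * se

    def test_degenerate_universe_gives_identical_distributions(self):
        cfg = SimulationConfig(universe=list(range(5)), list_sizes=[5, 5],
                               iterations=200, sampling="weighted", seed=31,
                               weights=np.arange(1.0, 6.0))
        cmp = compare_sampling_modes(cfg)
        assert np.array_equal(cmp.weighted.per_iteration_total_multi,
                              cmp.uniform.per_iteration_total_multi)


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "n_universe,list_sizes",
        [(6, (2, 3)), (8, (3, 3, 2)), (5, (2, 2, 2))],
    )
    def test_monte_carlo_matches_exhaustive_enumeration(self, n_universe, list_sizes):
        cfg = SimulationConfig(universe=list(range(n_universe)), list_sizes=list(list_sizes),
                               iterations=10_000, sampling="uniform", seed=37)
        null = simulate_null(cfg)
        dist = exact_overlap_distribution(n_universe, list_sizes)
        support = sorted(dist)
        for x in support[1:]:
            p_exact = sum(p for k, p in dist.items() if k >= x)
            p_hat = float((null.per_iteration_total_multi >= x).mean())
            se = math.sqrt(p_exact * (1 - p_exact) / cfg.iterations)
            assert abs(p_hat - p_exact) <= 3 * se + 1e-12


def test_overlap_total_from_lists_counts_multi_membership():
    assert overlap_total_from_lists([{1, 2, 3}, {2, 3, 4}, {3}]) == 2
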