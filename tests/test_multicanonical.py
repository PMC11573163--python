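"""Wang-Landau + entropic sampling against the exact enumeration oracle.

The two-gene, two-edge genotype space has exactly 24 members, so the density
of states per fitness bin, the within-bin composition and the chain's
stationary distribution can all be computed exactly and compared with the
sampler's output.
"""

import collections

import numpy as np
import pytest
from scipy import stats

from grnevo import (BinScheme, McmcConfig, WeightTable, enumeration_space,
                    entropic_sampling, fitness, fitness_bin,
                    genotypic_entropy, wang_landau)


@pytest.fixture(scope="module")
def oracle(params):
    """Exact per-bin composition of the 24-genotype space."""
    space = enumeration_space(2, 2)
    by_bin = collections.defaultdict(list)
    for g in space:
        by_bin[fitness_bin(fitness(g, params).f)].append(g.key())
    return {b: sorted(ks) for b, ks in by_bin.items()}


@pytest.fixture(scope="module")
def seed_genotype():
    return enumeration_space(2, 2)[0]


@pytest.fixture(scope="module")
def converged_weights(seed_genotype, params):
    cfg = McmcConfig(n_mcs=2_000_000, wl_final_increment=1e-4,
                     flatness_check_interval=2_000, seed=31)
    return wang_landau(seed_genotype, cfg, BinScheme(), params)


class TestFitnessBin:
    @pytest.mark.parametrize("f, expected", [
        (0.0, 0),
        (1.0, 99),          # clamped into the last bin
        (0.905, 90),
        (0.0099, 0),
        (0.01, 1),
    ])
    def test_examples(self, f, expected):
        assert fitness_bin(f) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fitness_bin(-0.1)
        with pytest.raises(ValueError):
            fitness_bin(1.5)

    def test_edges(self):
        assert BinScheme(100).edges(90) == (0.90, 0.91)


class TestWangLandau:
    def test_log_dos_matches_enumeration(self, converged_weights, oracle):
        ent = genotypic_entropy(converged_weights)
        n0 = len(oracle[0])
        for b, members in oracle.items():
            exact = np.log(len(members) / n0)
            assert ent[b] == pytest.approx(exact, abs=0.2)

    def test_only_real_bins_visited(self, converged_weights, oracle):
        visited = set(np.nonzero(converged_weights.visited)[0])
        assert visited == set(oracle)

    def test_budget_exhaustion_reported(self, seed_genotype, params):
        cfg = McmcConfig(n_mcs=5, wl_final_increment=1e-10,
                         flatness_check_interval=2, seed=1)
        w = wang_landau(seed_genotype, cfg, BinScheme(), params)
        assert not w.converged


class TestEntropicSampling:
    def test_within_bin_uniformity(self, seed_genotype, converged_weights,
                                   oracle, params):
        """In each bin every genotype of that bin appears equally often."""
        cfg = McmcConfig(n_mcs=100_000 * 20, sample_interval_mcs=20, seed=77)
        samples, _ = entropic_sampling(seed_genotype, converged_weights, cfg,
                                       params=params)
        assert len(samples) == 100_000
        counts = collections.defaultdict(collections.Counter)
        for i in range(len(samples)):
            counts[samples.extra["bin"][i]][samples.matrices[i].tobytes()] += 1
        for b, members in oracle.items():
            got = counts[b]
            assert set(got) == set(members), f"bin {b} composition differs"
            if len(members) > 1:
                _, p = stats.chisquare(list(got.values()))
                assert p > 0.01, f"bin {b} not uniform (p={p})"

    def test_flat_histogram_over_occupied_bins(self, seed_genotype,
                                               converged_weights, params):
        cfg = McmcConfig(n_mcs=100_000, sample_interval_mcs=20, seed=13)
        _, visits = entropic_sampling(seed_genotype, converged_weights, cfg,
                                      params=params)
        h = visits.histogram[visits.histogram > 0]
        assert h.min() / h.mean() >= 0.7

    def test_uniform_weights_give_uniform_genotype_distribution(
            self, seed_genotype, params):
        """With all-equal weights every proposal is accepted and the walk's
        stationary distribution is uniform over the 24 genotypes."""
        cfg = McmcConfig(n_mcs=100_000 * 2, sample_interval_mcs=2,
                         trials_per_mcs=2, seed=5)
        samples, _ = entropic_sampling(seed_genotype, WeightTable.uniform(),
                                       cfg, params=params)
        counter = collections.Counter(m.tobytes() for m in samples.matrices)
        assert len(counter) == 24
        _, p = stats.chisquare(list(counter.values()))
        assert p > 0.01

    def test_detailed_balance_of_fixed_weight_chain(self, seed_genotype,
                                                    converged_weights,
                                                    params):
        """Empirical flow between genotype pairs is symmetric."""
        cfg = McmcConfig(n_mcs=200_000, sample_interval_mcs=1,
                         trials_per_mcs=1, seed=21)
        samples, _ = entropic_sampling(seed_genotype, converged_weights, cfg,
                                       params=params)
        keys = [m.tobytes() for m in samples.matrices]
        flow = collections.Counter(zip(keys[:-1], keys[1:]))
        checked = 0
        for (a, b), n_ab in flow.items():
            if a >= b or n_ab < 100:
                continue
            n_ba = flow.get((b, a), 0)
            # symmetric flow within 4 sigma of the pooled estimate
            pooled = (n_ab + n_ba) / 2
            assert abs(n_ab - n_ba) < 4 * np.sqrt(2 * pooled) + 1
            checked += 1
        assert checked >= 5

    def test_identical_seeds_identical_samples(self, seed_genotype,
                                               converged_weights, params):
        cfg = McmcConfig(n_mcs=2_000, sample_interval_mcs=20, seed=99)
        a, _ = entropic_sampling(seed_genotype, converged_weights, cfg,
                                 params=params)
        b, _ = entropic_sampling(seed_genotype, converged_weights, cfg,
                                 params=params)
        assert [m.tobytes() for m in a.matrices] == \
               [m.tobytes() for m in b.matrices]
        assert a.fitness == b.fitness

    def test_stride_reduces_autocorrelation(self, seed_genotype,
                                            converged_weights, params):
        def lag1(bins):
            x = np.asarray(bins, dtype=float)
            x = x - x.mean()
            denom = (x * x).sum()
            return (x[:-1] * x[1:]).sum() / denom if denom else 0.0

        cfg1 = McmcConfig(n_mcs=30_000, sample_interval_mcs=1,
                          trials_per_mcs=2, seed=3)
        s1, _ = entropic_sampling(seed_genotype, converged_weights, cfg1,
                                  params=params)
        cfg20 = McmcConfig(n_mcs=30_000 * 20, sample_interval_mcs=20,
                           trials_per_mcs=2, seed=3)
        s20, _ = entropic_sampling(seed_genotype, converged_weights, cfg20,
                                   params=params)
        assert lag1(s20.extra["bin"]) < lag1(s1.extra["bin"])


def test_high_fitness_genotypes_are_exponentially_rare(smoke_study):
    """Desk-scale entropy curve: bins above f = 0.9 sit at least 10 natural-
    log units below bins under f = 0.1 (high fitness is a rare event)."""
    weights = smoke_study["weights"]
    ent = genotypic_entropy(weights)
    low = [ent[b] for b in range(10) if weights.visited[b]]
    high = [ent[b] for b in range(90, 100) if weights.visited[b]]
    assert low and high
    assert max(high) < min(low) - 10


class TestGenotypicEntropy:
    def test_normalised_to_lowest_bin(self, converged_weights):
        ent = genotypic_entropy(converged_weights)
        assert ent[0] == 0.0

    def test_unvisited_bins_are_nan(self, converged_weights):
        ent = genotypic_entropy(converged_weights)
        assert np.isnan(ent[50])

    def test_requires_lowest_bin(self):
        w = WeightTable(np.zeros(100), np.zeros(100, dtype=np.int64),
                        np.zeros(100, dtype=bool), 0.0)
        with pytest.raises(ValueError):
            genotypic_entropy(w)
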