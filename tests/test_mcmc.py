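import itertools

import numpy as np
import pytest

from burdenscan import McmcSubsetSearch, compute_weights, run_mc3
from burdenscan.base import SearchContext, kernel_weights, weighted_subset_sample
from burdenscan.mcmc import (
    ChainState,
    init_chains,
    mcmc_step,
    propose_swap,
    swap_move,
    temperature_ladder,
)

from conftest import make_genotypes


def _ctx(n=40, m=8, k=2, seed=0, kernel=None, null=False):
    G = make_genotypes(n, m, seed=seed)
    rng = np.random.default_rng(seed + 100)
    if null:
        y = rng.normal(size=n)
    else:
        y = G.counts[:, 0] + 0.5 * G.counts[:, 1] + rng.normal(size=n)
    w = compute_weights(G, kind="MB").weights
    return SearchContext(G.dosage(), w, y, k, kernel=kernel)


class TestTemperatureLadder:
    def test_default_five_chain_ladder(self):
        np.testing.assert_allclose(
            temperature_ladder(5), [1.0, 1 / 1.2, 1 / 1.4, 1 / 1.6, 1 / 1.8]
        )

    def test_cold_chain_is_unit_temperature(self):
        assert temperature_ladder(3)[0] == 1.0


class TestInitChains:
    def test_chain_count_and_subset_size(self):
        ctx = _ctx(k=3)
        chains = init_chains(ctx, n_chains=5, rng=np.random.default_rng(0))
        assert len(chains) == 5
        for c in chains:
            assert len(set(c.members.tolist())) == 3

    def test_full_set_when_k_equals_m(self):
        ctx = _ctx(m=6, k=6)
        chains = init_chains(ctx, n_chains=2, rng=np.random.default_rng(0))
        for c in chains:
            assert sorted(c.members.tolist()) == list(range(6))

    def test_uniform_kernel_gives_uniform_inclusion(self):
        # chi-square goodness of fit of initial membership counts
        ctx = _ctx(m=6, k=2, kernel=np.ones(6))
        counts = np.zeros(6)
        rng = np.random.default_rng(1)
        draws = 3000
        for _ in range(draws):
            counts[weighted_subset_sample(rng, ctx.kernel, 2)] += 1
        expected = draws * 2 / 6
        chi2 = np.sum((counts - expected) ** 2 / expected)
        # 5 df; 0.999 quantile ~ 20.5
        assert chi2 < 20.5

    def test_k_larger_than_m_rejected(self):
        with pytest.raises(ValueError):
            _ctx(m=5, k=6)


class TestProposeSwap:
    def test_uniform_kernel_has_zero_hastings_correction(self):
        ctx = _ctx(m=8, k=3, kernel=np.ones(8))
        chain = init_chains(ctx, 1, np.random.default_rng(2))[0]
        for _ in range(50):
            cand, log_h = propose_swap(chain, ctx, np.random.default_rng(_))
            assert log_h == pytest.approx(0.0)
            assert cand.k == 3

    def test_addition_probability_proportional_to_kernel(self):
        # subset {a}; non-members weights b=1, c=3 -> P(add c) = 0.75
        ctx = _ctx(m=3, k=1, kernel=np.array([5.0, 1.0, 3.0]))
        rng = np.random.default_rng(3)
        chain = ChainState(np.array([0]), ctx, 1.0)
        added = [propose_swap(chain, ctx, rng).__getitem__(0).as_array()[0] for _ in range(4000)]
        frac_c = np.mean(np.asarray(added) == 2)
        assert frac_c == pytest.approx(0.75, abs=0.03)


class TestMcmcStep:
    def test_flat_proposals_with_symmetric_kernel_always_accepted(self):
        # equal log-likelihood everywhere (all-zero genotypes) and a
        # uniform kernel: acceptance probability is exactly 1
        ctx = SearchContext(np.zeros((10, 8)), np.ones(8), np.arange(10.0), 2, kernel=np.ones(8))
        rng = np.random.default_rng(4)
        chain = ChainState(np.array([0, 1]), ctx, 1.0)
        assert all(mcmc_step(chain, ctx, rng) for _ in range(200))

    def test_uphill_move_accepted_at_any_temperature(self):
        ctx = _ctx(m=8, k=2, kernel=np.ones(8))
        rng = np.random.default_rng(4)
        for temp in (1.0, 0.5556):
            for trial in range(40):
                chain = init_chains(ctx, 1, rng)[0]
                chain.temperature = temp
                before_ll = chain.log_lik
                before_members = chain.members.copy()
                accepted = mcmc_step(chain, ctx, rng)
                if accepted:
                    continue  # downhill rejections are legitimate
                np.testing.assert_array_equal(chain.members, before_members)
                assert chain.log_lik == before_ll

    def test_cache_coherence_after_many_steps(self):
        ctx = _ctx(m=10, k=3)
        rng = np.random.default_rng(5)
        chain = init_chains(ctx, 1, rng)[0]
        for _ in range(500):
            mcmc_step(chain, ctx, rng)
        np.testing.assert_allclose(chain.score, ctx.score(chain.members), atol=1e-8)
        assert chain.r2 == pytest.approx(ctx.r2(ctx.score(chain.members)), abs=1e-10)
        assert chain.log_lik == pytest.approx(ctx.log_lik(chain.r2), abs=1e-8)

    def test_flat_likelihood_stationary_is_uniform(self):
        # all-zero genotypes: every subset scores 0, l = 0 everywhere; a
        # deliberately non-uniform kernel must still leave the uniform
        # distribution invariant thanks to the Hastings correction.
        m, k = 6, 2
        X = np.zeros((10, m))
        y = np.arange(10.0)
        kernel = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        ctx = SearchContext(X, np.ones(m), y, k, kernel=kernel)
        rng = np.random.default_rng(6)
        chain = ChainState(np.array([0, 1]), ctx, 1.0)
        counts: dict = {}
        steps = 60_000
        for _ in range(steps):
            mcmc_step(chain, ctx, rng)
            key = tuple(sorted(chain.members.tolist()))
            counts[key] = counts.get(key, 0) + 1
        n_subsets = 15  # C(6,2)
        freqs = np.array([counts.get(s, 0) / steps for s in itertools.combinations(range(m), k)])
        tv = 0.5 * np.sum(np.abs(freqs - 1.0 / n_subsets))
        assert tv < 0.05


class TestSwapMove:
    def test_equal_likelihood_swap_always_accepted(self):
        ctx = _ctx(m=8, k=2, kernel=np.ones(8))
        rng = np.random.default_rng(7)
        chains = init_chains(ctx, 2, rng)
        chains[1].log_lik = chains[0].log_lik
        assert swap_move(chains, rng)

    def test_better_subset_in_hotter_chain_always_swaps(self):
        ctx = _ctx(m=8, k=2)
        rng = np.random.default_rng(8)
        chains = init_chains(ctx, 2, rng)
        chains[1].log_lik = chains[0].log_lik + 5.0
        members_hot = chains[1].members.copy()
        assert swap_move(chains, rng)
        np.testing.assert_array_equal(chains[0].members, members_hot)
        # temperatures stay attached to positions
        assert chains[0].temperature == 1.0

    def test_single_chain_is_noop(self):
        ctx = _ctx()
        chains = init_chains(ctx, 1, np.random.default_rng(9))
        assert swap_move(chains, np.random.default_rng(9)) is False


class TestRunMc3:
    def test_fixed_seed_reproducibility(self):
        G = make_genotypes(50, 12, seed=10)
        y = G.counts[:, 3] + np.random.default_rng(0).normal(size=50)
        w = compute_weights(G, kind="LL")
        r1 = run_mc3(G, w, y, k=3, iterations=400, burn_in=100, rng_seed=123)
        r2 = run_mc3(G, w, y, k=3, iterations=400, burn_in=100, rng_seed=123)
        assert r1.best_subset.indices == r2.best_subset.indices
        np.testing.assert_array_equal(r1.inclusion_freq, r2.inclusion_freq)
        np.testing.assert_array_equal(r1.trace, r2.trace)

    def test_inclusion_frequencies_sum_to_k(self):
        G = make_genotypes(40, 10, seed=11)
        y = np.random.default_rng(1).normal(size=40)
        res = run_mc3(G, compute_weights(G, kind="LL"), y, k=4, iterations=300, burn_in=50, rng_seed=0)
        assert res.inclusion_freq.sum() == pytest.approx(4.0, abs=1e-9)
        assert np.all((res.inclusion_freq >= 0) & (res.inclusion_freq <= 1))

    def test_best_fitness_bounds_cold_chain_trace(self):
        G = make_genotypes(40, 10, seed=12)
        y = G.counts[:, 2] + np.random.default_rng(2).normal(size=40)
        res = run_mc3(G, compute_weights(G, kind="LL"), y, k=3, iterations=500, burn_in=0, rng_seed=1)
        from burdenscan.association import Fitness, log_likelihood

        best_ll = log_likelihood(res.best_fitness)
        assert np.all(res.trace <= best_ll + 1e-9)

    def test_strong_causal_variant_dominates_posterior(self):
        rng = np.random.default_rng(13)
        G = make_genotypes(150, 60, seed=13, maf_low=0.1, maf_high=0.4)
        g = G.counts[:, 7]
        # effect scaled so the variant explains ~half the trait variance
        y = g * (1.0 / g.std()) + rng.normal(size=150)
        hits = 0
        for seed in range(10):
            res = run_mc3(
                G, compute_weights(G, kind="LL"), y, k=5, iterations=1500, burn_in=300, rng_seed=seed
            )
            hits += res.inclusion_freq[7] > 0.9
        assert hits >= 9

    def test_null_trait_has_no_recurrent_false_positive(self):
        # any single null trait can concentrate the posterior on its
        # chance-best subset, but across independent null traits no variant
        # should be repeatedly implicated
        G = make_genotypes(100, 50, seed=14)
        mean_incl = 5 / 50
        incl = np.zeros(50)
        n_seeds = 8
        for seed in range(n_seeds):
            y = np.random.default_rng(1000 + seed).normal(size=100)
            res = run_mc3(
                G, compute_weights(G, kind="LL"), y, k=5, iterations=2000, burn_in=400, rng_seed=seed
            )
            incl += res.inclusion_freq
        assert (incl / n_seeds).max() < 5 * mean_incl

    def test_estimator_interface_round_trip(self):
        G = make_genotypes(60, 15, seed=15)
        y = G.counts[:, 4] + np.random.default_rng(3).normal(size=60)
        est = McmcSubsetSearch(
            statistic="MB", k=4, iterations=600, burn_in=100, random_state=7
        ).fit(G, y)
        assert est.get_support().sum() == 4
        assert est.transform(G).shape == (60, 1)
        assert 0 <= est.best_fitness_.r2 <= 1
        params = est.get_params()
        assert params["k"] == 4 and params["statistic"] == "MB"
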