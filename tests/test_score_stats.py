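import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burdenscan import GenotypeMatrix, SnpSubset, aggregate_score, compute_weights, marginal_effects
from burdenscan.score_stats import WeightScheme

from conftest import make_genotypes


def _matrix_from_counts(counts, mafs=None):
    counts = np.asarray(counts, dtype=float)
    m = counts.shape[1]
    return GenotypeMatrix(
        counts=counts,
        variant_ids=[f"v{j}" for j in range(m)],
        chromosome=["chr1"] * m,
        position=np.arange(1, m + 1),
        maf=mafs,
    )


class TestComputeWeights:
    def test_ll_weights_are_all_one(self, small_panel):
        w = compute_weights(small_panel, kind="LL")
        assert w.kind == "LL"
        np.testing.assert_array_equal(w.weights, 1.0)

    @pytest.mark.parametrize("maf,expected", [(0.05, 20.0), (0.5, 2.0), (0.25, 4.0)])
    def test_mb_weight_is_inverse_maf(self, maf, expected):
        G = _matrix_from_counts([[0.0], [1.0], [1.0]], mafs=[maf])
        w = compute_weights(G, kind="MB")
        assert w.weights[0] == pytest.approx(expected)

    def test_mb_monomorphic_variant_gets_zero_weight_with_warning(self):
        G = _matrix_from_counts([[0.0, 1.0], [0.0, 0.0], [0.0, 1.0]])
        with pytest.warns(UserWarning, match="monomorphic"):
            w = compute_weights(G, kind="MB")
        assert w.weights[0] == 0.0
        assert w.weights[1] > 0

    def test_mb_classical_form(self):
        # 1/sqrt(n q (1-q)) with n=4, q=0.25
        G = _matrix_from_counts([[0.0], [0.0], [1.0], [1.0]])
        w = compute_weights(G, kind="MB", classical=True)
        assert w.weights[0] == pytest.approx(1.0 / np.sqrt(4 * 0.25 * 0.75))

    def test_me_weight_on_three_point_toy(self):
        G = _matrix_from_counts([[0.0], [1.0], [2.0]])
        w = compute_weights(G, kind="ME", phenotype=np.array([0.0, 1.0, 2.0]))
        assert w.weights[0] == pytest.approx(1.0)

    def test_me_requires_phenotype(self, small_panel):
        with pytest.raises(ValueError, match="phenotype"):
            compute_weights(small_panel, kind="ME")

    def test_me_signed_flag_keeps_negative_effects(self):
        G = _matrix_from_counts([[0.0], [1.0], [2.0]])
        y = np.array([2.0, 1.0, 0.0])
        unsigned = compute_weights(G, kind="ME", phenotype=y)
        signed = compute_weights(G, kind="ME", phenotype=y, signed=True)
        assert unsigned.weights[0] == pytest.approx(1.0)
        assert signed.weights[0] == pytest.approx(-1.0)

    def test_unknown_kind_rejected(self, small_panel):
        with pytest.raises(ValueError):
            compute_weights(small_panel, kind="XX")


class TestMarginalEffects:
    def test_exact_ols_slope(self):
        G = _matrix_from_counts([[0.0], [1.0], [2.0]])
        beta = marginal_effects(G, np.array([1.0, 3.0, 5.0]))
        assert beta[0] == pytest.approx(2.0)

    def test_monomorphic_variant_effect_zero(self):
        G = _matrix_from_counts([[0.0, 0.0], [0.0, 1.0], [0.0, 2.0]])
        beta = marginal_effects(G, np.array([1.0, 2.0, 4.0]))
        assert beta[0] == 0.0
        assert beta[1] == pytest.approx(1.5)

    def test_constant_phenotype_is_error(self):
        G = _matrix_from_counts([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="constant"):
            marginal_effects(G, np.array([5.0, 5.0, 5.0]))

    def test_binary_log_odds_ratio_with_continuity_correction(self):
        # carriers: 3 cases, 1 control; non-carriers: 1 case, 3 controls
        counts = np.array([[1], [1], [2], [1], [0], [0], [0], [0]], dtype=float)
        y = np.array([1, 1, 1, 0, 1, 0, 0, 0], dtype=float)
        beta = marginal_effects(_matrix_from_counts(counts), y, trait_type="binary")
        assert beta[0] == pytest.approx(np.log(3 * 3 / (1 * 1)))


class TestAggregateScore:
    def test_unweighted_sum_of_counts(self):
        G = _matrix_from_counts([[0.0, 1.0, 2.0], [1.0, 0.0, 0.0], [2.0, 1.0, 1.0]])
        w = compute_weights(G, kind="LL")
        s = aggregate_score(G, SnpSubset.from_indices([0, 1, 2]), w)
        np.testing.assert_allclose(s, [3.0, 1.0, 4.0])

    def test_mb_weighted_example(self):
        G = _matrix_from_counts([[1.0, 1.0], [0.0, 1.0], [1.0, 0.0]], mafs=[0.05, 0.25])
        w = compute_weights(G, kind="MB")
        s = aggregate_score(G, SnpSubset.from_indices([0, 1]), w)
        assert s[0] == pytest.approx(24.0)  # 20*1 + 4*1

    def test_all_zero_genotypes_give_zero_scores(self):
        s = aggregate_score(np.zeros((4, 3)), np.array([0, 2]), np.ones(3))
        np.testing.assert_array_equal(s, 0.0)

    def test_missing_entries_contribute_zero(self):
        counts = np.array([[np.nan, 1.0], [1.0, 1.0], [0.0, 1.0]])
        G = _matrix_from_counts(counts)
        s = aggregate_score(G, SnpSubset.from_indices([0, 1]), np.ones(2))
        assert s[0] == pytest.approx(1.0)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            aggregate_score(np.zeros((3, 2)), np.array([], dtype=int), np.ones(2))

    def test_additive_over_disjoint_partitions(self, small_panel):
        w = compute_weights(small_panel, kind="MB")
        a, b = [0, 2, 4], [1, 5, 7]
        s_union = aggregate_score(small_panel, SnpSubset.from_indices(a + b), w)
        s_a = aggregate_score(small_panel, SnpSubset.from_indices(a), w)
        s_b = aggregate_score(small_panel, SnpSubset.from_indices(b), w)
        np.testing.assert_allclose(s_union, s_a + s_b)

    def test_mb_equals_scaled_ll_under_equal_mafs(self):
        rng = np.random.default_rng(11)
        counts = rng.binomial(2, 0.2, size=(30, 6)).astype(float)
        G = _matrix_from_counts(counts, mafs=np.full(6, 0.2))
        subset = SnpSubset.from_indices([1, 3, 4])
        s_ll = aggregate_score(G, subset, compute_weights(G, kind="LL"))
        s_mb = aggregate_score(G, subset, compute_weights(G, kind="MB"))
        np.testing.assert_allclose(s_mb, s_ll / 0.2)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 8))
    def test_variant_permutation_leaves_scores_unchanged(self, seed, k):
        rng = np.random.default_rng(seed)
        G = make_genotypes(25, 10, seed=seed % 1000)
        w = compute_weights(G, kind="MB").weights
        subset = rng.choice(10, size=k, replace=False)
        perm = rng.permutation(10)
        inv = np.argsort(perm)
        s = aggregate_score(G.counts, subset, w)
        s_perm = aggregate_score(G.counts[:, perm], inv[subset], w[perm])
        np.testing.assert_allclose(s, s_perm)


class TestSnpSubset:
    def test_size_invariant_enforced(self):
        with pytest.raises(ValueError):
            SnpSubset(indices=frozenset({1, 2}), k=3)

    def test_from_indices_deduplicates_to_error(self):
        s = SnpSubset.from_indices([3, 1, 2])
        assert s.k == 3
        np.testing.assert_array_equal(s.as_array(), [1, 2, 3])

    def test_weight_scheme_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            WeightScheme("LL", np.array([1.0, np.inf]))
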