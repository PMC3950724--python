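import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ganet import (
    ExpressionMatrix,
    ThresholdConfig,
    gaussian_kernel_mi,
    mi_from_correlation,
    pairwise_mi,
    permutation_pvalue,
    rank_transform,
    select_threshold,
    spearman_correlation,
)
from ganet.mi_engine import ConstantGeneWarning, EdgeSet, MIEdge


class TestRankTransform:
    def test_no_ties(self):
        assert rank_transform(np.array([0.1, 0.5, 0.3]))[0].tolist() == [1, 3, 2]

    def test_average_rank_ties(self):
        assert rank_transform(np.array([2.0, 2.0, 5.0]))[0].tolist() == [1.5, 1.5, 3]

    def test_row_sum_invariant(self, random_matrix):
        mat = random_matrix(n=10, m=17)
        ranks = rank_transform(mat)
        expected = 17 * 18 / 2
        np.testing.assert_allclose(ranks.sum(axis=1), expected)

    def test_monotone_transform_invariance(self, random_matrix):
        mat = random_matrix(n=5, m=20)
        transformed = np.exp(mat.values) ** 3
        np.testing.assert_array_equal(rank_transform(mat), rank_transform(transformed))

    def test_constant_row_flagged(self):
        with pytest.warns(ConstantGeneWarning):
            rank_transform(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))


class TestSpearman:
    def test_classic_textbook_value(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 24/120 = 0.8 for this permutation
        rho = spearman_correlation(
            np.array([1.0, 2, 3, 4, 5]), np.array([2.0, 1, 4, 3, 5])
        )
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 4])
        assert spearman_correlation(x, x * 10 + 3) == pytest.approx(1.0)

    def test_perfect_antimonotone(self):
        x = np.array([1.0, 2, 3, 4])
        assert spearman_correlation(x, x[::-1]) == pytest.approx(-1.0)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation(np.ones(5), np.arange(5.0))

    def test_matches_scipy_under_ties(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float)
        expected = spearmanr(x, y).statistic
        got = spearman_correlation(rank_transform(x)[0], rank_transform(y)[0])
        assert got == pytest.approx(expected, abs=1e-12)


class TestMIFromCorrelation:
    def test_zero_at_independence(self):
        assert mi_from_correlation(0.0) == 0.0

    def test_known_value(self):
        # -0.5 * ln(1 - 0.64) = 0.5108256237659907
        assert mi_from_correlation(0.8) == pytest.approx(0.510826, abs=1e-6)

    def test_sign_symmetry(self):
        assert mi_from_correlation(-0.8) == mi_from_correlation(0.8)

    def test_clamped_at_unity(self):
        # clamp |rho| to 1 - 1e-12, so 1 - rho^2 = 2e-12 - 1e-24
        v = mi_from_correlation(1.0)
        assert math.isfinite(v)
        # ~ -0.5*log(2e-12) up to double rounding of (1 - 1e-12)**2
        assert v == pytest.approx(-0.5 * math.log(2e-12), abs=1e-4)
        assert mi_from_correlation(-1.0) == v

    def test_domain_error(self):
        with pytest.raises(ValueError):
            mi_from_correlation(1.5)

    @given(st.floats(-1.0, 1.0))
    def test_nonnegative_and_monotone_in_magnitude(self, rho):
        v = mi_from_correlation(rho)
        assert v >= 0
        assert mi_from_correlation(min(1.0, abs(rho) + 0.01)) >= v


class TestPairwiseMI:
    def test_consistent_with_scalar_path(self, toy_matrix):
        edges = pairwise_mi(toy_matrix)
        assert len(edges) == 3
        ranks = rank_transform(toy_matrix)
        for e in edges:
            i = toy_matrix.gene_ids.index(e.gene_a)
            j = toy_matrix.gene_ids.index(e.gene_b)
            rho = spearman_correlation(ranks[i], ranks[j])
            assert e.mi == pytest.approx(mi_from_correlation(rho), abs=1e-12)

    def test_pair_count(self, random_matrix):
        mat = random_matrix(n=8, m=12)
        assert len(pairwise_mi(mat)) == 8 * 7 // 2

    def test_monotone_transform_bitwise_invariance(self, random_matrix):
        mat = random_matrix(n=12, m=25, seed=5)
        transformed = ExpressionMatrix(
            mat.gene_ids, mat.sample_ids, np.exp(mat.values)
        )
        e1 = pairwise_mi(mat).sorted_edges()
        e2 = pairwise_mi(transformed).sorted_edges()
        assert e1 == e2

    def test_worker_invariance_bitwise(self, random_matrix):
        mat = random_matrix(n=15, m=20, seed=2)
        base = pairwise_mi(mat, workers=1).sorted_edges()
        for w in (2, 8):
            assert pairwise_mi(mat, workers=w).sorted_edges() == base

    def test_constant_gene_dropped_with_warning(self, random_matrix):
        mat = random_matrix(n=4, m=10)
        vals = mat.values.copy()
        vals[1] = 7.0
        flat = ExpressionMatrix(mat.gene_ids, mat.sample_ids, vals)
        with pytest.warns(ConstantGeneWarning):
            edges = pairwise_mi(flat)
        assert len(edges) == 3
        assert all("g001" not in e.pair for e in edges)

    def test_too_few_usable_genes(self):
        vals = np.ones((2, 5))
        vals[0] = np.arange(5)
        mat = ExpressionMatrix(["g1", "g2"], [f"s{i}" for i in range(5)], vals)
        with pytest.raises(ValueError, match="non-constant"), pytest.warns(ConstantGeneWarning):
            pairwise_mi(mat)

    def test_planted_pair_detection_matches_independent_oracle(self):
        # Monte-Carlo oracle (scipy.stats.spearmanr, independent of the
        # package's path): one pair with rho=0.5, all others independent.
        # The oracle identifies the planted pair as strongest in 80/100
        # replicates at m=50; the package must agree replicate-by-replicate.
        from scipy.stats import spearmanr

        wins = oracle_wins = agreements = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=(10, 50))
            vals[1] = 0.5 * vals[0] + math.sqrt(1 - 0.25) * vals[1]
            mat = ExpressionMatrix(
                [f"g{i}" for i in range(10)], [f"s{j}" for j in range(50)], vals
            )
            edges = sorted(pairwise_mi(mat), key=lambda e: -e.mi)
            top = set(edges[0].pair)

            best, best_pair = -1.0, None
            for i in range(10):
                for j in range(i + 1, 10):
                    r = abs(spearmanr(vals[i], vals[j]).statistic)
                    if r > best:
                        best, best_pair = r, {f"g{i}", f"g{j}"}
            wins += top == {"g0", "g1"}
            oracle_wins += best_pair == {"g0", "g1"}
            agreements += top == best_pair
        assert agreements == 100
        assert wins == oracle_wins == 80


class TestGaussianKernelMI:
    def test_correlated_gaussian_near_analytic(self):
        rng = np.random.default_rng(11)
        z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=2000)
        mi = gaussian_kernel_mi(z[:, 0], z[:, 1])
        assert mi == pytest.approx(0.5108, abs=0.08)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(12)
        mi = gaussian_kernel_mi(rng.uniform(size=2000), rng.uniform(size=2000))
        assert abs(mi) <= 0.05

    def test_identical_vectors_dominate(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=500)
        noisy = x + rng.normal(0, 0.5, size=500)
        assert gaussian_kernel_mi(x, x) > gaussian_kernel_mi(x, noisy)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            gaussian_kernel_mi(np.ones(50), np.arange(50.0))

    def test_nonnegative(self):
        rng = np.random.default_rng(14)
        for seed in range(5):
            r = np.random.default_rng(seed)
            assert gaussian_kernel_mi(r.normal(size=100), r.normal(size=100)) >= 0


class TestPermutationPvalue:
    def test_perfect_monotone_floor(self):
        x = np.arange(100.0)
        config = ThresholdConfig(n_permutations=999, permutation_seed=0)
        obs = mi_from_correlation(1.0)
        assert permutation_pvalue(x, x * 2, obs, config) == pytest.approx(1 / 1000)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=100), rng.normal(size=100)
        config = ThresholdConfig(n_permutations=200, permutation_seed=42)
        p1 = permutation_pvalue(x, y, 0.05, config)
        p2 = permutation_pvalue(x, y, 0.05, config)
        assert p1 == p2

    def test_type_one_error_calibration(self):
        # independent pairs: P(p <= 0.05) should be ~0.05
        hits = 0
        config = ThresholdConfig(n_permutations=199, permutation_seed=0)
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=40), rng.normal(size=40)
            ranks = rank_transform(np.vstack([x, y]))
            obs = mi_from_correlation(spearman_correlation(ranks[0], ranks[1]))
            cfg = ThresholdConfig(n_permutations=199, permutation_seed=seed)
            if permutation_pvalue(x, y, obs, cfg) <= 0.05:
                hits += 1
        assert abs(hits / 200 - 0.05) <= 0.04


class TestSelectThreshold:
    def test_ten_percent_of_descending_hundred(self):
        assert select_threshold(range(1, 101), ThresholdConfig()) == 91

    def test_degenerate_all_equal(self):
        assert select_threshold([3.0] * 10, ThresholdConfig()) == 3.0

    def test_fraction_one_keeps_all(self):
        vals = [5.0, 1.0, 3.0]
        assert select_threshold(vals, ThresholdConfig(keep_top_fraction=1.0)) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_threshold([], ThresholdConfig())

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=50),
        st.floats(0.01, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_keep_count_contract(self, vals, fraction):
        config = ThresholdConfig(keep_top_fraction=fraction)
        thr = select_threshold(vals, config)
        kept = sum(1 for v in vals if v >= thr)
        want = math.ceil(fraction * len(vals))
        ties = sum(1 for v in vals if v == thr)
        assert want <= kept <= want + ties


class TestEdgeSet:
    def test_canonical_ordering(self):
        e = MIEdge.make("zzz", "aaa", rho=0.5)
        assert e.gene_a == "aaa" and e.gene_b == "zzz"

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            MIEdge.make("a", "a", rho=0.1)

    def test_round_trip_io(self, tmp_path):
        es = EdgeSet([MIEdge.make("a", "b", 0.5), MIEdge.make("b", "c", 0.9)])
        p = tmp_path / "edges.tsv"
        es.write(p, header_lines=["test"])
        back = EdgeSet.read(p)
        assert back.pairs() == es.pairs()
        assert back[("a", "b")].mi == pytest.approx(es[("a", "b")].mi, abs=1e-6)

    def test_duplicate_rejected(self):
        es = EdgeSet([MIEdge.make("a", "b", 0.5)])
        with pytest.raises(ValueError, match="duplicate"):
            es.add(MIEdge.make("b", "a", 0.2))
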