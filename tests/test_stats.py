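import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats

from oracles import spearman_exact_enum, tfce_reference, wilcoxon_exact_enum
from sensomap.stats import (TFCEParams, cluster_filter, permutation_fwe,
                            spearman, tfce_enhance, vertexwise_regression,
                            wilcoxon_signed_rank)


class TestVertexwiseRegression:
    def test_sign_flip_flips_t(self):
        rng = np.random.default_rng(0)
        maps = rng.standard_normal((12, 50))
        x = rng.standard_normal(12)
        t1 = vertexwise_regression(maps, x).t
        t2 = vertexwise_regression(maps, -x).t
        assert np.allclose(t1, -t2)

    def test_null_t_matches_student_distribution(self):
        rng = np.random.default_rng(1)
        n = 42
        maps = rng.standard_normal((n, 4000))
        x = rng.standard_normal(n)
        t = vertexwise_regression(maps, x).t
        # compare against the Student-t(n-2) CDF
        ks = scipy.stats.kstest(t, scipy.stats.t(df=n - 2).cdf)
        assert ks.pvalue > 0.01

    def test_degenerate_vertices_flagged(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(10)
        maps = rng.standard_normal((10, 5))
        maps[:, 1] = 3.0             # zero variance
        maps[:, 3] = 2.0 * x + 1.0   # exact fit
        res = vertexwise_regression(maps, x)
        assert res.t[1] == 0.0
        assert abs(res.t[3]) >= 1e6
        assert {1, 3} <= set(res.flagged.tolist())

    def test_preconditions(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="8 subjects"):
            vertexwise_regression(rng.standard_normal((5, 4)),
                                  rng.standard_normal(5))
        with pytest.raises(ValueError, match="variance"):
            vertexwise_regression(rng.standard_normal((10, 4)),
                                  np.ones(10))


class TestTfce:
    def test_single_vertex_analytic_value(self):
        adj = sp.csr_matrix((5, 5))
        vals = np.zeros(5)
        vals[2] = 1.0
        enh = tfce_enhance(vals, adj, TFCEParams(n_steps=100))
        # analytic limit: integral of h^H dh = h^(H+1)/(H+1) = 1/3
        assert enh[2] == pytest.approx(1.0 / 3.0, rel=0.02)

    def test_uniform_map_symmetric_scores(self, mesh162):
        enh = tfce_enhance(np.full(mesh162.n_vertices, 2.0),
                           mesh162.adjacency, TFCEParams())
        assert np.allclose(enh, enh[0])

    def test_matches_per_threshold_reference(self, mesh162):
        rng = np.random.default_rng(4)
        vals = np.abs(rng.standard_normal(mesh162.n_vertices))
        params = TFCEParams(n_steps=60)
        mine = tfce_enhance(vals, mesh162.adjacency, params)
        ref = tfce_reference(vals, mesh162.adjacency, params.E, params.H,
                             params.n_steps)
        assert np.allclose(mine, ref, rtol=1e-10, atol=1e-12)

    def test_two_tailed_antisymmetry(self, mesh162):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal(mesh162.n_vertices)
        enh = tfce_enhance(vals, mesh162.adjacency, TFCEParams())
        enh_neg = tfce_enhance(-vals, mesh162.adjacency, TFCEParams())
        assert np.allclose(enh, -enh_neg)

    def test_monotonicity(self, mesh162):
        """On a fixed threshold grid, pointwise-larger maps never lose
        enhancement anywhere."""
        rng = np.random.default_rng(6)
        params = TFCEParams(dh=0.05)
        x = np.abs(rng.standard_normal(mesh162.n_vertices))
        bump = np.abs(rng.standard_normal(mesh162.n_vertices))
        a = tfce_enhance(x, mesh162.adjacency, params)
        b = tfce_enhance(x + bump, mesh162.adjacency, params)
        assert (b >= a - 1e-9).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TFCEParams(E=-1.0)
        with pytest.raises(ValueError):
            TFCEParams(n_steps=0)
        with pytest.raises(ValueError):
            TFCEParams(n_permutations=10)


class TestPermutationFwe:
    def test_seeded_reproducibility(self, mesh162):
        rng = np.random.default_rng(7)
        maps = rng.standard_normal((12, mesh162.n_vertices))
        x = rng.standard_normal(12)
        params = TFCEParams(n_permutations=100)
        p1 = permutation_fwe(maps, x, mesh162.adjacency, params,
                             rng_seed=3).p_fwe
        p2 = permutation_fwe(maps, x, mesh162.adjacency, params,
                             rng_seed=3).p_fwe
        assert np.array_equal(p1, p2)
        p3 = permutation_fwe(maps, x, mesh162.adjacency, params,
                             rng_seed=4).p_fwe
        assert not np.array_equal(p1, p3)

    def test_add_one_estimator_never_zero(self, mesh162):
        rng = np.random.default_rng(8)
        maps = rng.standard_normal((10, mesh162.n_vertices))
        maps[:, 40] += 10 * rng.standard_normal(10)[0] * 0 + \
            5 * np.arange(10)
        x = np.arange(10.0)
        res = permutation_fwe(maps, x, mesh162.adjacency,
                              TFCEParams(n_permutations=200), rng_seed=0)
        assert res.p_fwe.min() >= 1.0 / 201.0

    def test_exact_enumeration_for_tiny_cohorts(self, mesh162):
        """With n! below the permutation budget the group is enumerated."""
        rng = np.random.default_rng(9)
        n = 8  # regression requires >= 8 subjects
        maps = rng.standard_normal((n, 30))
        x = rng.standard_normal(n)
        adj = sp.csr_matrix((30, 30))
        params = TFCEParams(n_permutations=50000)
        res = permutation_fwe(maps, x, adj, params, rng_seed=0)
        # p-values are multiples of 1/8! and valid probabilities
        import math
        frac = res.p_fwe * math.factorial(n)
        assert np.allclose(frac, np.round(frac), atol=1e-6)
        assert (res.p_fwe > 0).all() and (res.p_fwe <= 1).all()


class TestClusterFilter:
    def test_empty_when_nothing_significant(self, mesh642):
        p = np.ones(mesh642.n_vertices)
        assert len(cluster_filter(p, mesh642.adjacency)) == 0

    def test_extent_reported_and_floor_applied(self, mesh642):
        p = np.ones(mesh642.n_vertices)
        big = mesh642.nearest_vertices(10, 60)
        p[big] = 0.01
        tab = cluster_filter(p, mesh642.adjacency, alpha=0.05, k_min=50)
        assert len(tab) == 1
        assert tab.iloc[0]["k_e"] == 60
        assert tab.iloc[0]["peak_vertex"] in big
        small = np.ones(mesh642.n_vertices)
        small[mesh642.nearest_vertices(10, 40)] = 0.01
        assert len(cluster_filter(small, mesh642.adjacency,
                                  k_min=50)) == 0


class TestSpearman:
    def test_perfect_anticorrelation(self):
        r = spearman([1, 2, 3], [3, 2, 1])
        assert r.statistic == pytest.approx(-1.0)

    def test_monotone_transform(self):
        x = np.array([0.3, 1.2, 2.0, 5.5, 9.0])
        r = spearman(x, np.exp(x))
        assert r.statistic == pytest.approx(1.0)

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(10)
        for n in (5, 6, 7):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            mine = spearman(x, y)
            _, p_ref = spearman_exact_enum(x, y)
            assert mine.p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_p_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0])
        mine = spearman(x, y)
        _, p_ref = spearman_exact_enum(x, y)
        assert mine.p == pytest.approx(p_ref, abs=1e-12)

    def test_bonferroni_and_flags(self):
        r = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], n_comparisons=3)
        assert r.p_bonferroni == pytest.approx(min(1.0, 3 * r.p))
        degenerate = spearman(np.ones(6), np.arange(6.0))
        assert degenerate.flagged and np.isnan(degenerate.p)


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        r = wilcoxon_signed_rank(np.arange(6.0), np.arange(6.0))
        assert r.flagged and r.p == 1.0

    def test_all_positive_n6_exact(self):
        a = np.arange(1.0, 7.0)
        r = wilcoxon_signed_rank(a + 1.0, a)
        assert r.p == pytest.approx(2.0 / 64.0)

    def test_mixed_signs_match_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            d = rng.standard_normal(10)
            r = wilcoxon_signed_rank(d, np.zeros(10))
            w_ref, p_ref = wilcoxon_exact_enum(d)
            assert r.statistic == pytest.approx(w_ref)
            assert r.p == pytest.approx(p_ref, abs=1e-12)

    def test_tied_ranks_match_enumeration(self):
        d = np.array([1.0, -1.0, 2.0, 2.0, -3.0, 4.0, 4.0])
        r = wilcoxon_signed_rank(d, np.zeros(7))
        _, p_ref = wilcoxon_exact_enum(d)
        assert r.p == pytest.approx(p_ref, abs=1e-12)

    def test_large_n_uses_corrected_normal_approximation(self):
        rng = np.random.default_rng(12)
        a = rng.standard_normal(40) + 0.3
        b = np.zeros(40)
        mine = wilcoxon_signed_rank(a, b)
        ref = scipy.stats.wilcoxon(a - b, alternative="two-sided",
                                   method="approx", correction=True)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_minimum_size(self):
        with pytest.raises(ValueError, match="at least 5"):
            wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0, 4.0]),
                                 np.zeros(4))
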