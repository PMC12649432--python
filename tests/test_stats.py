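import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quieteye.stats import (
    bootstrap_p,
    cca,
    descriptives,
    pearson_with_t,
    permutation_p,
    shared_variance,
    shared_variance_pvalue,
    wilks_sequential,
)

from oracles import cca_oracle


def orthonormal_columns(n, k, seed=0):
    """Zero-mean, unit-variance, exactly orthogonal columns."""
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n, k))
    Q, _ = np.linalg.qr(M - M.mean(axis=0))
    Q -= Q.mean(axis=0)  # re-centre (QR does not preserve zero means)
    Q, _ = np.linalg.qr(Q)
    return Q * np.sqrt(n - 1)


class TestDescriptives:
    def test_symmetric_sequence(self):
        d = descriptives(np.array([1, 2, 3, 4, 5], float))
        assert (d.q1, d.median, d.q3) == (2, 3, 4)
        assert d.skewness == pytest.approx(0.0, abs=1e-12)
        assert d.minimum == 1 and d.maximum == 5

    def test_right_skew_is_positive(self):
        assert descriptives(np.array([1, 1, 1, 10], float)).skewness > 0

    def test_constant_vector_is_flagged(self):
        d = descriptives(np.full(5, 3.0))
        assert d.skewness is None and d.shapiro_p is None

    def test_shapiro_p_roughly_uniform_under_normality(self):
        rng = np.random.default_rng(42)
        ps = [descriptives(rng.standard_normal(200)).shapiro_p for _ in range(200)]
        # under H0 the p-values are U(0,1): mean near 0.5, ~10% below 0.1
        assert abs(np.mean(ps) - 0.5) < 0.08
        assert 0.03 < np.mean(np.array(ps) < 0.1) < 0.18


class TestPearsonWithT:
    def test_perfect_correlations(self):
        up = pearson_with_t(np.array([1, 2, 3.0]), np.array([2, 4, 6.0]))
        down = pearson_with_t(np.array([1, 2, 3.0]), np.array([6, 4, 2.0]))
        assert up.r == pytest.approx(1.0)
        assert down.r == pytest.approx(-1.0)

    def test_t_reference_for_moderate_negative_r(self):
        # exact construction: r = -0.417 at n = 57
        n, r = 57, -0.417
        Q = orthonormal_columns(n, 2, seed=3)
        x = Q[:, 0]
        y = r * Q[:, 0] + np.sqrt(1 - r * r) * Q[:, 1]
        rep = pearson_with_t(x, y)
        assert rep.r == pytest.approx(r, abs=1e-12)
        assert abs(rep.t_stat) == pytest.approx(3.402, abs=0.002)
        assert rep.p_t < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_t(np.ones(10), np.arange(10.0))


class TestBootstrapP:
    def test_collinear_pair_hits_floor(self):
        x = np.arange(20.0)
        p = bootstrap_p(x, 2 * x + 1, B=999, seed=0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 30))
        assert bootstrap_p(x, y, B=499, seed=11) == bootstrap_p(x, y, B=499, seed=11)

    def test_small_B_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_p(np.arange(10.0), np.arange(10.0), B=50)


class TestSharedVariance:
    def test_single_predictor_equals_r_squared(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        y = 0.4 * x + rng.standard_normal(40)
        r = pearson_with_t(x, y).r
        sv = shared_variance(y, x)
        assert sv.r_squared == pytest.approx(r * r, abs=1e-12)

    def test_orthogonal_predictors_add_r_squared(self):
        n = 200
        Q = orthonormal_columns(n, 3, seed=7)
        y = 0.3 * Q[:, 0] + 0.4 * Q[:, 1] + np.sqrt(1 - 0.09 - 0.16) * Q[:, 2]
        sv = shared_variance(y, Q[:, :2])
        assert sv.r_squared == pytest.approx(0.25, abs=1e-12)

    def test_adding_a_predictor_never_lowers_r_squared(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((50, 4))
        y = X @ [0.5, -0.2, 0.0, 0.1] + rng.standard_normal(50)
        r2 = [shared_variance(y, X[:, : k + 1]).r_squared for k in range(4)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_rank_deficient_predictors_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(30)
        X = np.column_stack([x, 2 * x, rng.standard_normal(30)])
        with pytest.raises(ValueError, match="rank"):
            shared_variance(rng.standard_normal(30), X)

    @pytest.mark.parametrize(
        "r2, expected_p",
        [(0.206, 0.016), (0.160, 0.055), (0.144, 0.082)],
    )
    def test_pvalue_back_calculation(self, r2, expected_p):
        # the reported R² is itself rounded to 3 decimals, so the implied
        # p-value interval over the rounding band must reach the reported p
        p_lo = shared_variance_pvalue(r2 + 0.0005, k=4, n=57)
        p_hi = shared_variance_pvalue(r2 - 0.0005, k=4, n=57)
        assert p_lo - 0.0005 <= expected_p <= p_hi + 0.0005
        assert shared_variance_pvalue(r2, k=4, n=57) == pytest.approx(expected_p, abs=0.0015)

    def test_pvalue_helper_matches_fit(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((57, 4))
        y = X @ [0.3, 0.1, -0.2, 0.0] + rng.standard_normal(57)
        sv = shared_variance(y, X)
        assert shared_variance_pvalue(sv.r_squared, sv.k, sv.n) == pytest.approx(sv.p_f, rel=1e-9)


class TestCCA:
    def test_identical_single_columns_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((30, 1))
        res = cca(x, x.copy())
        assert res.canonical_correlations[0] == pytest.approx(1.0, abs=1e-9)

    def test_one_dimensional_sets_recover_absolute_r(self):
        n, r = 100, -0.5
        Q = orthonormal_columns(n, 2, seed=4)
        x = Q[:, :1]
        y = (r * Q[:, 0] + np.sqrt(1 - r * r) * Q[:, 1])[:, None]
        res = cca(x, y)
        assert res.canonical_correlations[0] == pytest.approx(0.5, abs=1e-9)
        # the canonical pair correlates positively, so the loadings of the
        # two observed variables must carry the sign of r between them
        assert res.loadings_X[0, 0] * res.loadings_Y[0, 0] == pytest.approx(-1.0, abs=1e-9)

    def test_recovers_constructed_population_correlations(self):
        rng = np.random.default_rng(12)
        n = 20000
        z = rng.standard_normal((n, 2))
        e = rng.standard_normal((n, 2))
        X = z.copy()
        Y = np.column_stack(
            [0.6 * z[:, 0] + np.sqrt(1 - 0.36) * e[:, 0],
             0.2 * z[:, 1] + np.sqrt(1 - 0.04) * e[:, 1]]
        )
        # mix within sets: CCA is invariant to invertible within-set maps
        A = np.array([[1.0, 0.3], [-0.5, 0.8]])
        B = np.array([[0.7, -0.2], [0.4, 1.1]])
        res = cca(X @ A, Y @ B)
        np.testing.assert_allclose(res.canonical_correlations, [0.6, 0.2], atol=0.02)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_eigen_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        X = rng.standard_normal((n, 4))
        Y = 0.3 * X @ rng.standard_normal((4, 6)) + rng.standard_normal((n, 6))
        res = cca(X, Y)
        np.testing.assert_allclose(
            res.canonical_correlations, cca_oracle(X, Y), atol=1e-8
        )

    def test_invariant_to_affine_column_rescaling(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((50, 3))
        Y = rng.standard_normal((50, 4))
        res1 = cca(X, Y)
        X2 = X * [3.0, 0.1, 5.0] + [10.0, -2.0, 0.5]
        res2 = cca(X2, Y)
        np.testing.assert_allclose(
            res1.canonical_correlations, res2.canonical_correlations, atol=1e-10
        )
        np.testing.assert_allclose(res1.loadings_X, res2.loadings_X, atol=1e-8)

    def test_squared_loadings_sum_at_most_one(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((57, 4))
        Y = rng.standard_normal((57, 6))
        res = cca(X, Y)
        assert np.all((res.loadings_X**2).sum(axis=1) <= 1 + 1e-9)
        assert np.all((res.loadings_Y**2).sum(axis=1) <= 1 + 1e-9)

    def test_sign_convention_orients_largest_loading_positive(self):
        rng = np.random.default_rng(31)
        X = rng.standard_normal((80, 3))
        Y = rng.standard_normal((80, 3))
        res = cca(X, Y)
        for j in range(3):
            stacked = np.concatenate([res.loadings_X[:, j], res.loadings_Y[:, j]])
            assert stacked[np.argmax(np.abs(stacked))] > 0

    def test_collinear_set_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(40)
        X = np.column_stack([x, x + 1e-12 * rng.standard_normal(40)])
        with pytest.raises(ValueError, match="ill-conditioned|constant"):
            cca(X, rng.standard_normal((40, 2)))


class TestWilksSequential:
    def test_reported_canonical_pair_values(self):
        lam = wilks_sequential(np.array([0.584, 0.400]))
        assert lam[0] == pytest.approx(0.5535, abs=5e-5)
        assert lam[1] == pytest.approx(0.8400, abs=1e-12)

    def test_null_and_degenerate_cases(self):
        np.testing.assert_allclose(wilks_sequential(np.zeros(4)), np.ones(4))
        assert wilks_sequential(np.array([1.0, 0.3]))[0] == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            wilks_sequential(np.array([1.2]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 0.999), min_size=1, max_size=6))
    def test_reconstructs_from_descending_products(self, rhos):
        rhos = np.sort(np.asarray(rhos))[::-1]
        lam = wilks_sequential(rhos)
        direct = [np.prod(1 - rhos[k:] ** 2) for k in range(len(rhos))]
        np.testing.assert_allclose(lam, direct, rtol=1e-12)
        assert np.all(np.diff(lam) >= -1e-12)  # increases toward 1


class TestPermutationP:
    def test_maximal_association_hits_floor(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((57, 4))
        Y = X[:, [2, 0, 3, 1]]
        p = permutation_p(X, Y, B=199, seed=0)
        assert p[0] == pytest.approx(1.0 / 200.0)

    def test_bounds_and_determinism(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((40, 3))
        Y = rng.standard_normal((40, 5))
        p1 = permutation_p(X, Y, B=299, seed=7)
        p2 = permutation_p(X, Y, B=299, seed=7)
        np.testing.assert_array_equal(p1, p2)
        assert np.all(p1 >= 1.0 / 300.0) and np.all(p1 <= 1.0)

    def test_small_B_rejected(self):
        with pytest.raises(ValueError):
            permutation_p(np.ones((10, 2)), np.ones((10, 2)), B=10)
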