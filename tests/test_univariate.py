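import numpy as np
import pytest
from scipy import stats

from nbstab import (
    StatMap,
    group_ttest,
    r_to_t,
    residualize,
    threshold_map,
    voxelwise_corr,
)
from nbstab.univariate import T_CAP


class TestResidualize:
    def test_zero_variance_covariate_rejected(self, rng):
        y = rng.standard_normal(10)
        with pytest.raises(ValueError, match="rank-deficient"):
            residualize(y, np.zeros((10, 1)))

    def test_orthogonal_input_unchanged(self, rng):
        n = 20
        C = rng.standard_normal((n, 2))
        v = rng.standard_normal(n)
        v0 = residualize(v, C)  # already-residualized values
        assert np.allclose(residualize(v0, C), v0, atol=1e-10)  # projection idempotent

    def test_exact_covariate_gives_zero(self, rng):
        age = rng.standard_normal(15)
        resid = residualize(2.0 * age, age)
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_residuals_orthogonal_to_covariates(self, rng):
        n = 30
        C = rng.standard_normal((n, 2))
        V = rng.standard_normal((n, 7))
        R = residualize(V, C)
        scale = np.abs(V).max()
        assert np.all(np.abs(C.T @ R) < 1e-8 * scale * n)
        assert np.all(np.abs(R.sum(axis=0)) < 1e-8 * scale * n)

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError, match="rows"):
            residualize(rng.standard_normal(3), rng.standard_normal((3, 2)))


class TestVoxelwiseCorr:
    def test_perfect_correlations(self, rng):
        y = rng.standard_normal(10)
        X = np.column_stack([y, -y, rng.standard_normal(10)])
        m = voxelwise_corr(X, y)
        assert m.values[0] == pytest.approx(1.0)
        assert m.values[1] == pytest.approx(-1.0)

    def test_sum_formula_oracle(self, rng):
        # independent brute-force: r = (n Sxy - Sx Sy) / sqrt((n Sxx - Sx^2)(n Syy - Sy^2))
        n = 6
        X = rng.standard_normal((n, 4))
        y = rng.standard_normal(n)
        m = voxelwise_corr(X, y)
        for v in range(4):
            x = X[:, v]
            num = n * (x * y).sum() - x.sum() * y.sum()
            den = np.sqrt((n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2))
            assert m.values[v] == pytest.approx(num / den, abs=1e-12)

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            voxelwise_corr(rng.standard_normal((8, 3)), np.full(8, 2.0))

    def test_zero_variance_voxel_flagged(self, rng):
        X = rng.standard_normal((8, 3))
        X[:, 1] = 5.0
        m = voxelwise_corr(X, rng.standard_normal(8))
        assert m.values[1] == 0.0
        assert m.flags[1] and not m.flags[0]

    def test_affine_invariance(self, rng):
        X = rng.standard_normal((12, 5))
        y = rng.standard_normal(12)
        a = voxelwise_corr(X, y).values
        b = voxelwise_corr(3.0 * X - 1.0, -0.5 * y + 7.0).values
        assert np.allclose(np.abs(a), np.abs(b), atol=1e-12)
        assert np.allclose(b, -a, atol=1e-12)  # negative y scaling flips sign

    def test_residualize_then_correlate_equals_partial_correlation(self, rng):
        # oracle: partial r from the full 3-variable correlation matrix
        n = 50
        c = rng.standard_normal(n)
        x = 0.5 * c + rng.standard_normal(n)
        y = -0.3 * c + rng.standard_normal(n)
        r_impl = voxelwise_corr(residualize(x[:, None], c), residualize(y, c)).values[0]
        R = np.corrcoef(np.column_stack([x, y, c]).T)
        r_xy, r_xc, r_yc = R[0, 1], R[0, 2], R[1, 2]
        r_partial = (r_xy - r_xc * r_yc) / np.sqrt((1 - r_xc**2) * (1 - r_yc**2))
        assert r_impl == pytest.approx(r_partial, abs=1e-10)


class TestRtoT:
    def test_zero_maps_to_zero(self):
        m = StatMap(values=np.zeros(3), kind="r", n=20)
        assert np.all(r_to_t(m).values == 0.0)

    def test_closed_form_value(self):
        m = StatMap(values=np.array([0.5]), kind="r", n=18)
        t = r_to_t(m)  # df = 16
        assert t.df == 16
        assert t.values[0] == pytest.approx(0.5 * np.sqrt(16 / 0.75), abs=1e-12)

    def test_monotone_in_r(self):
        r = np.linspace(-0.99, 0.99, 101)
        t = r_to_t(StatMap(values=r, kind="r", n=30)).values
        assert np.all(np.diff(t) > 0)

    def test_unit_r_capped(self):
        t = r_to_t(StatMap(values=np.array([1.0, -1.0]), kind="r", n=10))
        assert t.values[0] == T_CAP and t.values[1] == -T_CAP

    def test_df_accounts_for_covariates(self):
        m = StatMap(values=np.array([0.1]), kind="r", n=10)
        assert r_to_t(m, q_covariates=2).df == 6

    def test_df_too_small(self):
        m = StatMap(values=np.array([0.1]), kind="r", n=4)
        with pytest.raises(ValueError, match="df"):
            r_to_t(m, q_covariates=2)


class TestGroupTtest:
    def test_constant_nonzero_capped(self):
        X = np.full((5, 2), 3.0)
        t = group_ttest(X)
        assert np.all(t.values == T_CAP)
        assert t.flags.all()

    def test_symmetric_values_give_zero(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        assert group_ttest(X).values[0] == 0.0

    def test_matches_reference_ttest(self, rng):
        X = rng.standard_normal((5, 3)) + 0.5
        t = group_ttest(X)
        ref = stats.ttest_1samp(X, 0.0, axis=0).statistic
        assert np.allclose(t.values, ref, atol=1e-12)
        assert t.df == 4

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            group_ttest(np.ones((1, 3)))


class TestThreshold:
    def test_inclusive_positive(self):
        m = StatMap(values=np.array([2.9, 3.0, 3.1]), kind="t", n=20, df=18)
        assert threshold_map(m, 3.0).sum() == 2

    def test_all_below_empty(self):
        m = StatMap(values=np.array([0.1, -0.5]), kind="t", n=20, df=18)
        assert not threshold_map(m, 3.0).any()

    def test_absolute_is_union(self, rng):
        m = StatMap(values=rng.standard_normal(50) * 3, kind="t", n=20, df=18)
        pos = threshold_map(m, 2.0, "positive")
        neg = threshold_map(m, 2.0, "negative")
        assert np.array_equal(threshold_map(m, 2.0, "absolute"), pos | neg)

    def test_flagged_voxels_excluded(self):
        m = StatMap(
            values=np.array([5.0, 5.0]), kind="t", n=20, df=18,
            flags=np.array([False, True]),
        )
        assert list(threshold_map(m, 3.0)) == [True, False]

    def test_nonfinite_threshold_rejected(self):
        m = StatMap(values=np.zeros(2), kind="t", n=5, df=3)
        with pytest.raises(ValueError):
            threshold_map(m, np.inf)
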