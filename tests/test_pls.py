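import itertools

import numpy as np
import pytest

from nbstab import bootstrap_bsr, fit_pls, permutation_pvalue, run_behavioral_pls
from nbstab.univariate import _corr_columns


def make_exact_corr_design(weights, y=None, n=8, seed=0):
    """Build X whose empirical voxel-behavior correlations equal `weights`.

    Each column is w*z + sqrt(1-w^2)*u with z the standardized (centered,
    unit-norm) behavior and u unit vectors orthogonal to z and to each other.
    """
    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, dtype=float)
    if y is None:
        y = rng.standard_normal(n)
    z = y - y.mean()
    z /= np.linalg.norm(z)
    basis = [z, np.ones(n) / np.sqrt(n)]
    cols = []
    for w in weights:
        u = rng.standard_normal(n)
        for b in basis:
            u -= (u @ b) * b
        u /= np.linalg.norm(u)
        basis.append(u)
        cols.append(w * z + np.sqrt(1 - w**2) * u)
    return np.column_stack(cols), y


class TestFitPls:
    def test_pythagorean_salience(self):
        X, y = make_exact_corr_design([0.6, 0.8])
        res = fit_pls(X, y)
        assert res.singular_value == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(res.salience, [0.6, 0.8], atol=1e-12)

    def test_voxel_equal_to_behavior(self, rng):
        y = rng.standard_normal(10)
        res = fit_pls(y[:, None], y)
        assert np.allclose(res.salience, [1.0])
        assert res.r_brainscore_behavior == pytest.approx(1.0)

    def test_closed_form_equals_svd(self, rng):
        for _ in range(10):
            X = rng.standard_normal((8, 5))
            y = rng.standard_normal(8)
            res = fit_pls(X, y)
            r = np.array([np.corrcoef(X[:, v], y)[0, 1] for v in range(5)])
            u, s, vt = np.linalg.svd(r[None, :], full_matrices=False)
            assert res.singular_value == pytest.approx(s[0], abs=1e-10)
            sal = vt[0] * np.sign(vt[0] @ res.salience)
            assert np.allclose(res.salience, sal, atol=1e-10)

    def test_brainscore_correlation_nonnegative(self, rng):
        for seed in range(5):
            r2 = np.random.default_rng(seed)
            X = r2.standard_normal((12, 20))
            y = r2.standard_normal(12)
            assert fit_pls(X, y).r_brainscore_behavior >= 0

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_pls(rng.standard_normal((8, 3)), np.ones(8))

    def test_all_zero_correlation_rejected(self):
        X = np.full((8, 3), 7.0)  # every voxel constant -> r identically 0
        y = np.arange(8.0)
        with pytest.raises(ValueError, match="undefined"):
            fit_pls(X, y)


class TestPermutationP:
    def test_strong_signal_minimal_p(self, rng):
        y = rng.standard_normal(60)
        X = np.column_stack([y, y, rng.standard_normal(60)])
        p = permutation_pvalue(X, y, n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)

    def test_exact_enumeration_oracle(self, rng):
        # n = 5: all 120 permutations enumerable; Monte-Carlo must agree
        X = rng.standard_normal((5, 6))
        y = rng.standard_normal(5)
        s_obs = fit_pls(X, y).singular_value
        svals = np.array(
            [
                np.linalg.norm(_corr_columns(X, y[list(p)])[0])
                for p in itertools.permutations(range(5))
            ]
        )
        p_exact = np.mean(svals >= s_obs * (1 - 1e-9))
        p_mc = permutation_pvalue(X, y, n_perm=10_000, seed=2)
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(p_mc - p_exact) <= 3 * se + 2 / 10_001

    def test_affine_y_invariance(self, rng):
        X = rng.standard_normal((15, 10))
        y = rng.standard_normal(15)
        p1 = permutation_pvalue(X, y, n_perm=100, seed=3)
        p2 = permutation_pvalue(X, 5.0 * y - 2.0, n_perm=100, seed=3)
        assert p1 == p2

    def test_p_in_unit_interval(self, rng):
        X = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        p = permutation_pvalue(X, y, n_perm=50, seed=4)
        assert 0 < p <= 1


class TestBootstrapBsr:
    def test_exactly_zero_observed_correlation(self, rng):
        # voxel orthogonal to behavior: r_obs = 0 exactly -> bsr = 0
        X, y = make_exact_corr_design([0.0, 0.5], n=40, seed=5)
        bsr, flags = bootstrap_bsr(X, y, n_boot=1000, seed=6)
        assert abs(bsr[0]) < 0.5
        assert not flags.any()

    def test_true_signal_exceeds_three(self):
        # rho = 0.5 at n = 100: the BSR behaves like a z score and the
        # population z is ~5, so the detection rate should be high
        hits = 0
        for i in range(10):
            r2 = np.random.default_rng(100 + i)
            z = r2.standard_normal(100)
            X = np.column_stack(
                [0.5 * z + np.sqrt(0.75) * r2.standard_normal(100)]
                + [r2.standard_normal(100) for _ in range(9)]
            )
            bsr, _ = bootstrap_bsr(X, z, n_boot=1000, seed=200 + i)
            hits += bsr[0] > 3
        assert hits >= 9

    def test_stable_under_more_replicates(self, rng):
        X = rng.standard_normal((50, 5))
        y = rng.standard_normal(50)
        b1, _ = bootstrap_bsr(X, y, n_boot=500, seed=7)
        b2, _ = bootstrap_bsr(X, y, n_boot=1000, seed=7)
        assert np.all(np.abs(b1 - b2) < 1.0)  # Monte-Carlo jitter only

    def test_n_boot_floor(self, rng):
        with pytest.raises(ValueError):
            bootstrap_bsr(rng.standard_normal((10, 2)), rng.standard_normal(10), n_boot=1)


class TestRunBehavioralPls:
    def test_defaults_recorded(self, rng):
        X = rng.standard_normal((10, 5))
        y = rng.standard_normal(10)
        res = run_behavioral_pls(X, y, n_perm=20, n_boot=20, seed=1)
        assert res.n_perm == 20 and res.n_boot == 20 and res.seed == 1
        assert res.bsr.shape == (5,)

    def test_standard_resampling_defaults(self):
        import inspect

        sig = inspect.signature(run_behavioral_pls)
        assert sig.parameters["n_perm"].default == 1000
        assert sig.parameters["n_boot"].default == 1000

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((12, 6))
        y = rng.standard_normal(12)
        a = run_behavioral_pls(X, y, n_perm=50, n_boot=50, seed=9)
        b = run_behavioral_pls(X, y, n_perm=50, n_boot=50, seed=9)
        assert a.perm_p == b.perm_p
        assert np.array_equal(a.bsr, b.bsr)
        assert np.array_equal(a.salience, b.salience)
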