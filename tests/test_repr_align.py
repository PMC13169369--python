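"""Linear CKA, minimum-norm OLS, numerical rank, and the performance-gap bound."""

import numpy as np
import pytest

from apdkit.repr_align import (
    FeatureMatrix,
    ResponseVector,
    bound_experiment,
    center_columns,
    check_bound,
    linear_cka,
    numeric_rank,
    ols_fit,
)
from conftest import random_centered


def hsic_cka_oracle(X: np.ndarray, Z: np.ndarray) -> float:
    """Independent Gram-matrix (HSIC-form) oracle for linear CKA.

    trace(Kc Lc) / sqrt(trace(Kc Kc) * trace(Lc Lc)) with K = X X^T,
    L = Z Z^T, both double-centered.
    """
    n = X.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    Kc = H @ (X @ X.T) @ H
    Lc = H @ (Z @ Z.T) @ H
    return np.trace(Kc @ Lc) / np.sqrt(np.trace(Kc @ Kc) * np.trace(Lc @ Lc))


class TestCenterColumns:
    def test_constant_column_becomes_zero(self):
        out = center_columns(np.full((4, 1), 5.0))
        assert np.allclose(out.values, 0.0)
        assert out.centered

    def test_idempotent_on_centered_matrix(self, rng):
        M = rng.standard_normal((6, 3))
        once = center_columns(M)
        twice = center_columns(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_single_column_mean_subtraction(self):
        out = center_columns(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(out.values.ravel(), [-1.0, 1.0])

    def test_rejects_single_row_and_nonfinite(self):
        with pytest.raises(ValueError):
            center_columns(np.ones((1, 3)))
        with pytest.raises(ValueError):
            center_columns(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestLinearCKA:
    def test_self_alignment_is_one(self, rng):
        X = random_centered(rng, 12, 4)
        assert linear_cka(X, X).value == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_cross_covariance_gives_zero(self):
        ids = (0, 1, 2, 3)
        X = center_columns(np.array([1.0, -1.0, 0.0, 0.0])[:, None], ids)
        Z = center_columns(np.array([0.0, 0.0, 1.0, -1.0])[:, None], ids)
        assert linear_cka(X, Z).value == pytest.approx(0.0, abs=1e-15)

    def test_matches_hsic_gram_oracle(self, centered_pair):
        X, Z = centered_pair
        expected = hsic_cka_oracle(X.values, Z.values)
        assert linear_cka(X, Z).value == pytest.approx(expected, abs=1e-10)

    def test_matches_oracle_on_many_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 30))
            X = random_centered(rng, n, int(rng.integers(1, 8)))
            Z = random_centered(rng, n, int(rng.integers(1, 8)))
            expected = hsic_cka_oracle(X.values, Z.values)
            assert linear_cka(X, Z).value == pytest.approx(expected, abs=1e-10)

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            X = random_centered(rng, 15, 4)
            Z = random_centered(rng, 15, 6)
            v1 = linear_cka(X, Z).value
            v2 = linear_cka(Z, X).value
            assert v1 == pytest.approx(v2, abs=1e-12)
            assert 0.0 <= v1 <= 1.0 + 1e-10

    def test_orthogonal_and_scaling_invariance(self, rng):
        X = random_centered(rng, 20, 5)
        Z = random_centered(rng, 20, 4)
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        XQ = FeatureMatrix(X.values @ Q, X.sample_ids, centered=True)
        cX = FeatureMatrix(3.7 * X.values, X.sample_ids, centered=True)
        base = linear_cka(X, Z).value
        assert abs(linear_cka(XQ, Z).value - base) <= 1e-8
        assert abs(linear_cka(cX, Z).value - base) <= 1e-8

    def test_errors_on_mismatch_and_degenerate(self, rng):
        X = random_centered(rng, 10, 3)
        Z = random_centered(rng, 11, 3)
        with pytest.raises(ValueError, match="mismatch"):
            linear_cka(X, Z)
        Zero = FeatureMatrix(np.zeros((10, 2)), X.sample_ids, centered=True)
        with pytest.raises(ValueError, match="degenerate"):
            linear_cka(X, Zero)


class TestOLSFit:
    def test_invertible_design_interpolates(self, rng):
        X = FeatureMatrix(rng.standard_normal((5, 5)), tuple(range(5)))
        y = ResponseVector(rng.standard_normal(5))
        assert ols_fit(X, y).residual_sq_norm == pytest.approx(0.0, abs=1e-18)

    def test_orthonormal_design_coefficients(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((10, 4)))
        X = FeatureMatrix(Q, tuple(range(10)))
        y = ResponseVector(rng.standard_normal(10))
        fit = ols_fit(X, y)
        np.testing.assert_allclose(fit.coefficients, Q.T @ y.values, atol=1e-12)

    def test_rank_deficient_matches_pseudoinverse_oracle(self, rng):
        base = rng.standard_normal((20, 4))
        design = np.column_stack([base, base[:, 0], base[:, 1]])  # two duplicates
        X = center_columns(design)
        yv = rng.standard_normal(20)
        y = ResponseVector(yv)
        fit = ols_fit(X, y)
        beta = np.linalg.pinv(X.values) @ yv
        resid = X.values @ beta - yv
        assert fit.residual_sq_norm == pytest.approx(resid @ resid, abs=1e-10)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)

    def test_residual_orthogonal_to_columns(self, rng):
        X = random_centered(rng, 15, 4)
        y = ResponseVector(rng.standard_normal(15))
        fit = ols_fit(X, y)
        resid = X.values @ fit.coefficients - y.values
        np.testing.assert_allclose(X.values.T @ resid, 0.0, atol=1e-10)

    def test_dimension_mismatch(self, rng):
        X = random_centered(rng, 10, 3)
        with pytest.raises(ValueError):
            ols_fit(X, ResponseVector(rng.standard_normal(9)))


class TestNumericRank:
    @pytest.mark.parametrize(
        "matrix,expected",
        [
            (np.zeros((3, 3)), 0),
            (np.eye(3), 3),
            (np.outer([1.0, 2.0, 3.0], [4.0, 5.0]), 1),
        ],
    )
    def test_known_ranks(self, matrix, expected):
        assert numeric_rank(matrix) == expected

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            numeric_rank(np.empty((0, 0)))


class TestBound:
    def test_identical_designs(self, rng):
        X = random_centered(rng, 12, 4)
        chk = check_bound(X, X, rng.standard_normal(12))
        assert chk.lhs == pytest.approx(0.0, abs=1e-12)
        assert chk.alignment == pytest.approx(1.0, abs=1e-10)
        assert chk.rhs == pytest.approx(2 * chk.rank_x - 2, abs=1e-8)
        assert chk.holds

    def test_orthogonal_rotation_of_design(self, rng):
        X = random_centered(rng, 15, 5)
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        Z = FeatureMatrix(X.values @ Q, X.sample_ids, centered=True)
        chk = check_bound(X, Z, rng.standard_normal(15))
        assert chk.lhs == pytest.approx(0.0, abs=1e-10)
        assert chk.alignment == pytest.approx(1.0, abs=1e-10)
        assert chk.holds

    def test_swap_negates_lhs_preserves_rhs(self, rng):
        X = random_centered(rng, 20, 6)
        Z = random_centered(rng, 20, 3)
        y = rng.standard_normal(20)
        a = check_bound(X, Z, y)
        b = check_bound(Z, X, y)
        assert b.lhs == pytest.approx(-a.lhs, abs=1e-10)
        assert b.rhs == pytest.approx(a.rhs, abs=1e-10)

    def test_holds_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 60))
            X = random_centered(rng, n, int(rng.integers(1, 20)))
            Z = random_centered(rng, n, int(rng.integers(1, 20)))
            chk = check_bound(X, Z, rng.standard_normal(n))
            assert chk.holds


class TestBoundExperiment:
    def test_small_run_has_no_violations(self):
        s = bound_experiment(50, seed=7)
        assert s.n_violations == 0
        assert all(v >= -1e-8 for v in s.slack_quantiles.values())

    def test_same_seed_reproduces_summary(self):
        a = bound_experiment(25, seed=3)
        b = bound_experiment(25, seed=3)
        assert a == b

    def test_rejects_zero_trials(self):
        with pytest.raises(ValueError):
            bound_experiment(0)
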