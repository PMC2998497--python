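"""Spearman, partial rank correlation, OLS, PCA, Mann-Whitney, Fisher."""

import numpy as np
import pytest

from ppi_evorate.stats import (
    DegenerateInputError,
    fisher_exact,
    mann_whitney,
    multivariate_regression,
    partial_spearman,
    pca_determinants,
    spearman,
)
from ppi_evorate.stats import _partial_from_corr  # white-box: formula check
from ._oracles import (
    eigh_oracle,
    fisher_exact_enumeration,
    mann_whitney_exact_enumeration,
    partial_corr_recursion,
    spearman_rho,
)


class TestSpearman:
    def test_perfect_anticorrelation(self):
        assert spearman([1, 2, 3], [3, 2, 1]).rho == -1.0

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=50)
        assert spearman(x, np.exp(3 * x) + 5).rho == pytest.approx(1.0, abs=1e-12)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100) + 0.5 * x
        x[:10] = x[0]  # inject ties to exercise average ranking
        res = spearman(x, y)
        assert res.rho == pytest.approx(spearman_rho(list(x), list(y)), abs=1e-12)
        assert res.n == 100

    def test_exact_small_sample_p(self):
        # n = 3: of the 6 pairings, only identity and reversal reach |rho| = 1
        res = spearman([1, 2, 3], [3, 2, 1])
        assert res.p_value == pytest.approx(2 / 6, abs=1e-12)

    def test_constant_vector_error(self):
        with pytest.raises(DegenerateInputError):
            spearman([1.0, 1.0, 1.0], [1, 2, 3])

    def test_too_short_error(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [2, 1])

    def test_p_floor_for_display(self, rng):
        x = np.arange(100.0)
        res = spearman(x, x + rng.normal(scale=0.01, size=100), p_floor=1e-6)
        assert res.p_value == 1e-6


class TestPartialSpearman:
    def test_single_control_recursion_formula_all_half(self):
        corr = np.array([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1.0]])
        assert _partial_from_corr(corr) == pytest.approx(1 / 3, abs=1e-12)
        assert partial_corr_recursion(0.5, 0.5, 0.5) == pytest.approx(1 / 3, abs=1e-15)

    def test_uncorrelated_control_reduces_to_simple(self):
        corr = np.array([[1, 0.42, 0.0], [0.42, 1, 0.0], [0.0, 0.0, 1.0]])
        assert _partial_from_corr(corr) == pytest.approx(0.42, abs=1e-12)

    def test_empty_control_set_equals_spearman(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert partial_spearman(x, y, controls=[]).rho == pytest.approx(
            spearman(x, y).rho, abs=1e-12
        )

    def test_inversion_equals_residualization(self, rng):
        for _ in range(10):
            n = 100
            z1, z2 = rng.normal(size=n), rng.normal(size=n)
            x = z1 + rng.normal(size=n)
            y = -z1 + 0.5 * z2 + rng.normal(size=n)
            a = partial_spearman(x, y, [z1, z2], method="inversion").rho
            b = partial_spearman(x, y, [z1, z2], method="residualization").rho
            assert a == pytest.approx(b, abs=1e-10)

    def test_matches_recursion_on_measured_rank_correlations(self, rng):
        n = 60
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = z + rng.normal(size=n)
        r_xy = spearman(x, y).rho
        r_xz = spearman(x, z).rho
        r_yz = spearman(y, z).rho
        expected = partial_corr_recursion(r_xy, r_xz, r_yz)
        assert partial_spearman(x, y, [z]).rho == pytest.approx(expected, abs=1e-10)

    def test_control_identical_to_y_degenerate(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        with pytest.raises(DegenerateInputError):
            partial_spearman(x, y, [y])

    def test_p_uses_reduced_degrees_of_freedom(self, rng):
        x, y, z = rng.normal(size=30), rng.normal(size=30), rng.normal(size=30)
        res = partial_spearman(x, y, [z])
        simple = spearman(x, y)
        assert res.controls == ("z1",)
        assert 0 < res.p_value <= 1
        assert res.n == simple.n


class TestMultivariateRegression:
    def test_exact_linear_combination_recovered(self, rng):
        n = 50
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 2.0 * x1 - 3.0 * x2 + 1.0
        res = multivariate_regression(y, {"x1": x1, "x2": x2}, standardize=False)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.predictor("x1").coefficient == pytest.approx(2.0, abs=1e-8)
        assert res.predictor("x2").coefficient == pytest.approx(-3.0, abs=1e-8)
        assert res.intercept == pytest.approx(1.0, abs=1e-8)

    def test_single_predictor_t_squared_equals_f(self, rng):
        import statsmodels.api as sm

        n = 40
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        res = multivariate_regression(y, {"x": x})
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.predictor("x").t_value ** 2 == pytest.approx(fit.fvalue, rel=1e-10)

    def test_standardization_leaves_t_and_p_unchanged(self, rng):
        n = 60
        x1, x2 = rng.normal(size=n), rng.exponential(size=n) * 100
        y = x1 + 0.01 * x2 + rng.normal(size=n)
        raw = multivariate_regression(y, {"x1": x1, "x2": x2}, standardize=False)
        std = multivariate_regression(y, {"x1": x1, "x2": x2}, standardize=True)
        for name in ("x1", "x2"):
            assert raw.predictor(name).t_value == pytest.approx(
                std.predictor(name).t_value, rel=1e-8
            )
            assert raw.predictor(name).p_value == pytest.approx(
                std.predictor(name).p_value, rel=1e-8
            )

    def test_null_predictor_type_i_error_calibrated(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            n = 50
            signal = rng.normal(size=n)
            noise_pred = rng.normal(size=n)
            y = signal + rng.normal(size=n)
            res = multivariate_regression(y, {"signal": signal, "noise": noise_pred})
            rejections += res.predictor("noise").p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_collinear_design_error(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(DegenerateInputError):
            multivariate_regression(rng.normal(size=30), {"a": x, "b": 2 * x})


class TestPCA:
    def test_independent_columns_near_unit_eigenvalues(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5000, 3))
        res = pca_determinants(X)
        assert np.all(np.abs(res.eigenvalues - 1.0) < 0.1)
        assert res.eigenvalues.sum() == pytest.approx(3.0, abs=1e-10)

    def test_two_perfectly_correlated_columns(self, rng):
        x = rng.normal(size=200)
        res = pca_determinants(np.column_stack([x, 3 * x + 1]))
        assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)
        assert list(res.retained) == [True, False]

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(150, 3))
        X[:, 1] += X[:, 0]
        res = pca_determinants(X, variable_names=("a", "b", "c"))
        corr = np.corrcoef((X - X.mean(0)) / X.std(0, ddof=1), rowvar=False)
        eigvals, eigvecs = eigh_oracle(corr)
        assert res.eigenvalues == pytest.approx(eigvals, abs=1e-10)
        assert res.loadings == pytest.approx(eigvecs, abs=1e-10)

    def test_reconstruction_and_orthonormality(self, rng):
        X = rng.normal(size=(80, 4))
        X[:, 2] -= 0.7 * X[:, 3]
        res = pca_determinants(X)
        corr = np.corrcoef((X - X.mean(0)) / X.std(0, ddof=1), rowvar=False)
        rebuilt = res.loadings @ np.diag(res.eigenvalues) @ res.loadings.T
        assert rebuilt == pytest.approx(corr, abs=1e-10)
        assert res.loadings.T @ res.loadings == pytest.approx(np.eye(4), abs=1e-10)

    def test_sign_orientation_largest_loading_positive(self, rng):
        X = rng.normal(size=(60, 3))
        res = pca_determinants(X)
        for j in range(3):
            col = res.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_scores_project_standardized_data(self, rng):
        X = rng.normal(size=(50, 3))
        res = pca_determinants(X)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        assert res.scores == pytest.approx(Z @ res.loadings, abs=1e-12)

    def test_constant_column_degenerate(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        with pytest.raises(DegenerateInputError):
            pca_determinants(X)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        u_oracle, p_oracle = mann_whitney_exact_enumeration([1, 2, 3], [4, 5, 6])
        assert (res.u_statistic, res.p_value) == (u_oracle, pytest.approx(p_oracle))

    def test_exact_matches_enumeration_on_random_small_samples(self, rng):
        for _ in range(20):
            pooled = rng.choice(1000, size=8, replace=False).astype(float)
            a, b = pooled[:4], pooled[4:]
            res = mann_whitney(a, b)
            u_oracle, p_oracle = mann_whitney_exact_enumeration(a, b)
            assert res.u_statistic == u_oracle
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_identical_samples_p_near_one(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0] * 5, [1.0, 2.0, 3.0, 4.0] * 5)
        assert res.p_value > 0.9

    def test_large_sample_matches_permutation_oracle(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(loc=0.35, size=80)
        res = mann_whitney(a, b)
        pooled = np.concatenate([a, b])
        mean_u = a.size * b.size / 2
        obs_dev = abs(res.u_statistic - mean_u)
        count = 0
        n_shuffles = 10_000
        for _ in range(n_shuffles):
            rng.shuffle(pooled)
            ranks = np.argsort(np.argsort(pooled)) + 1
            u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2
            count += abs(u - mean_u) >= obs_dev
        mc_p = count / n_shuffles
        mc_err = 3 * np.sqrt(max(mc_p, 1e-4) * (1 - mc_p) / n_shuffles)
        assert res.p_value == pytest.approx(mc_p, abs=max(0.01, mc_err))

    def test_group_means_and_sizes_reported(self):
        res = mann_whitney([1.0, 3.0], [10.0], group_names=("low", "high"))
        assert res.group_means == (2.0, 10.0)
        assert res.group_sizes == (2, 1)
        assert 0 <= res.u_statistic <= 2 * 1

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestFisherExact:
    def test_diagonal_table(self):
        assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3, abs=1e-12)

    def test_uniform_table(self):
        assert fisher_exact([[1, 1], [1, 1]]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_oracle_on_small_tables(self):
        for a in range(5):
            for b in range(5):
                for c in range(5):
                    for d in range(5):
                        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                            continue
                        table = [[a, b], [c, d]]
                        assert fisher_exact(table) == pytest.approx(
                            fisher_exact_enumeration(table), abs=1e-12
                        ), table

    def test_zero_margin_error(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [1, 2]])

    def test_non_integer_error(self):
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])
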