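"""Null fit, residualisation, score components, eigen reduction and the JST.

Oracles: explicit normal-equation solves for the weighted regressions, a
direct matrix-inverse Hotelling statistic for the full-rank case, and
statsmodels' logistic fit for the null model.
"""

import numpy as np
import pytest
from scipy import stats

from jst.jst_core import (
    PairedCohort,
    ScoreComponents,
    SeparationError,
    eigen_reduce,
    fit_null,
    jst_statistic,
    jst_test,
    residualize,
    score_components,
)
from jst.matching_scores import gene_score
from jst.simulator import GenotypeModel, make_cohort


def _random_cohort(seed, n=150, m=6, outcome="binary"):
    rng = np.random.default_rng(seed)
    model = GenotypeModel(m=m, maf=np.linspace(0.1, 0.4, m), block_sizes=(m,), rho=0.4)
    X_R, X_D = make_cohort(model, n, rng)
    W = np.column_stack([rng.binomial(1, 0.5, n), rng.standard_normal(n)])
    lp = -0.8 + 0.5 * W[:, 0] + 0.5 * W[:, 1]
    if outcome == "binary":
        Y = rng.binomial(1, 1 / (1 + np.exp(-lp))).astype(float)
    else:
        Y = lp + rng.standard_normal(n)
    Z = gene_score(X_D, X_R, "ibs").z
    return PairedCohort(Y=Y, W=W, X=X_R.astype(float), Z=Z, outcome_type=outcome)


class TestFitNull:
    def test_intercept_only_binary_is_mean(self):
        Y = np.array([0, 0, 1, 1, 1, 0, 1, 0], float)
        nf = fit_null(Y, np.empty((8, 0)), "binary")
        np.testing.assert_allclose(nf.fitted_mean, Y.mean(), atol=1e-8)
        np.testing.assert_allclose(nf.weights, Y.mean() * (1 - Y.mean()), atol=1e-8)

    def test_intercept_only_continuous_is_mean_and_sample_variance(self):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal(40) * 2 + 1
        nf = fit_null(Y, np.empty((40, 0)), "continuous")
        np.testing.assert_allclose(nf.fitted_mean, Y.mean())
        np.testing.assert_allclose(nf.residual_variance, Y.var(ddof=1))

    def test_logistic_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n = 400
        W = np.column_stack([rng.binomial(1, 0.5, n), rng.standard_normal(n)])
        p = 1 / (1 + np.exp(-(-0.5 + 0.7 * W[:, 0] - 0.3 * W[:, 1])))
        Y = rng.binomial(1, p).astype(float)
        nf = fit_null(Y, W, "binary")
        ref = sm.GLM(Y, sm.add_constant(W), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(nf.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(nf.fitted_mean, ref.fittedvalues, atol=1e-6)

    def test_intercept_recovers_logit_prevalence(self):
        rng = np.random.default_rng(5)
        Y = rng.binomial(1, 0.10, size=30000).astype(float)
        nf = fit_null(Y, np.empty((30000, 0)), "binary")
        assert abs(nf.coefficients[0] - np.log(0.10 / 0.90)) < 0.1

    def test_separation_fails_with_diagnostic(self):
        W = np.linspace(-1, 1, 30)[:, None]
        Y = (W.ravel() > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_null(Y, W, "binary")

    def test_singular_covariates_fail(self):
        rng = np.random.default_rng(1)
        W = np.repeat(rng.standard_normal((20, 1)), 2, axis=1)
        Y = rng.binomial(1, 0.5, 20).astype(float)
        with pytest.raises(ValueError, match="rank"):
            fit_null(Y, W, "binary")


class TestResidualize:
    def test_intercept_only_unit_weights_centers_columns(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, (50, 4)).astype(float)
        Z = rng.integers(0, 5, 50).astype(float)
        design = residualize(X, Z, np.empty((50, 0)), np.ones(50))
        expected = np.column_stack([X - X.mean(0), Z - Z.mean()])
        np.testing.assert_allclose(design.B_res, expected, atol=1e-10)

    def test_constant_column_residual_is_zero(self):
        X = np.ones((30, 1)) * 2
        Z = np.arange(30, dtype=float)
        design = residualize(X, Z, np.empty((30, 0)), np.ones(30))
        np.testing.assert_allclose(design.B_res[:, 0], 0, atol=1e-10)

    def test_weighted_case_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        n = 60
        W = rng.standard_normal((n, 2))
        X = rng.integers(0, 3, (n, 3)).astype(float)
        Z = rng.integers(0, 4, n).astype(float)
        w = rng.uniform(0.05, 0.25, n)
        design = residualize(X, Z, W, w)
        A = np.column_stack([np.ones(n), W])
        B = np.column_stack([X, Z])
        theta = np.linalg.solve(A.T @ (A * w[:, None]), A.T @ (B * w[:, None]))
        np.testing.assert_allclose(design.B_res, B - A @ theta, atol=1e-10)

    def test_weighted_orthogonality_invariant(self):
        rng = np.random.default_rng(6)
        n = 80
        W = rng.standard_normal((n, 2))
        X = rng.integers(0, 3, (n, 4)).astype(float)
        Z = rng.integers(0, 4, n).astype(float)
        w = rng.uniform(0.05, 0.25, n)
        B_res = residualize(X, Z, W, w).B_res
        A = np.column_stack([np.ones(n), W])
        gram = (B_res * w[:, None]).T @ A
        np.testing.assert_allclose(gram, 0, atol=1e-8)


class TestScoreComponents:
    def test_perfect_null_fit_gives_zero_scores(self):
        from jst.jst_core import NullFit

        rng = np.random.default_rng(8)
        Y = rng.standard_normal(25)
        nf = NullFit(
            fitted_mean=Y.copy(), weights=np.ones(25), coefficients=np.zeros(1),
            outcome_type="continuous", residual_variance=1.0,
        )
        design = residualize(rng.integers(0, 3, (25, 3)).astype(float),
                             rng.integers(0, 4, 25).astype(float),
                             np.empty((25, 0)), np.ones(25))
        comp = score_components(Y, nf, design)
        np.testing.assert_allclose(comp.U, 0, atol=1e-12)
        np.testing.assert_allclose(comp.V_hat, 0, atol=1e-12)

    def test_six_pair_toy_table_hand_computation(self):
        """Single SNP, no covariates: U_1 is the classic score-test numerator."""
        Y = np.array([1, 0, 1, 0, 0, 1], float)
        x = np.array([2, 0, 1, 1, 0, 2], float)
        z = np.array([1, 0, 2, 0, 1, 1], float)
        nf = fit_null(Y, np.empty((6, 0)), "binary")
        design = residualize(x[:, None], z, np.empty((6, 0)), nf.weights)
        comp = score_components(Y, nf, design)
        p_bar = Y.mean()
        u1_hand = np.sum((x - x.mean()) * (Y - p_bar))
        np.testing.assert_allclose(comp.U[0], u1_hand, atol=1e-8)
        # V_hat entries are plain sums of per-pair products
        for a in range(2):
            for b in range(2):
                np.testing.assert_allclose(
                    comp.V_hat[a, b], np.sum(comp.Q[:, a] * comp.Q[:, b]), atol=1e-12
                )
        np.testing.assert_allclose(comp.U, comp.Q.sum(axis=0), atol=1e-12)

    def test_continuous_intercept_only_matches_centered_cross_products(self):
        cohort = _random_cohort(9, outcome="continuous")
        nf = fit_null(cohort.Y, np.empty((cohort.n, 0)), "continuous")
        design = residualize(cohort.X, cohort.Z, np.empty((cohort.n, 0)), nf.weights)
        comp = score_components(cohort.Y, nf, design)
        yc = cohort.Y - cohort.Y.mean()
        for j in range(cohort.m):
            xc = cohort.X[:, j] - cohort.X[:, j].mean()
            np.testing.assert_allclose(comp.U[j], np.sum(xc * yc), atol=1e-8)


class TestEigenReduce:
    def test_identity_matrix_equal_eigenvalues(self):
        red = eigen_reduce(np.eye(4), 0.65)
        assert red.s == 3  # cumulative fractions 0.25, 0.5, 0.75, 1.0

    @pytest.mark.parametrize("threshold,expected_s", [(0.85, 1), (0.95, 2), (1.0, 2)])
    def test_diag_9_1_closed_form(self, threshold, expected_s):
        red = eigen_reduce(np.diag([9.0, 1.0]), threshold)
        assert red.s == expected_s
        np.testing.assert_allclose(red.lambdas, [9.0, 1.0][: red.s])

    def test_eigenvalues_sorted_and_diagonalization(self):
        rng = np.random.default_rng(10)
        A = rng.standard_normal((40, 5))
        V = A.T @ A
        red = eigen_reduce(V, 1.0)
        assert np.all(np.diff(red.lambdas) <= 1e-9)
        np.testing.assert_allclose(
            red.A_s.T @ V @ red.A_s, np.diag(red.lambdas), atol=1e-8
        )

    def test_zero_matrix_fails(self):
        with pytest.raises(ValueError):
            eigen_reduce(np.zeros((3, 3)), 0.8)

    def test_numerically_null_eigenvalues_dropped(self):
        # rank-2 matrix embedded in 4 dims: the two null directions never count
        rng = np.random.default_rng(12)
        A = rng.standard_normal((30, 2))
        V = np.zeros((4, 4))
        V[:2, :2] = A.T @ A
        red = eigen_reduce(V, 1.0)
        assert red.s == 2


class TestJSTStatistic:
    @staticmethod
    def _components_from_Q(Q):
        return ScoreComponents(U=Q.sum(axis=0), Q=Q, V_hat=Q.T @ Q)

    def test_zero_score_vector_gives_zero_statistic(self):
        rng = np.random.default_rng(13)
        Q = rng.standard_normal((40, 5))
        Q -= Q.mean(axis=0)  # columns sum to zero -> U = 0
        comp = self._components_from_Q(Q)
        red = eigen_reduce(comp.V_R, 1.0)
        res = jst_statistic(comp, red)
        assert res.statistic == pytest.approx(0.0, abs=1e-18)
        assert res.p_value == pytest.approx(1.0)

    def test_block_diagonal_oracle_when_score_uncorrelated(self):
        rng = np.random.default_rng(14)
        Q = rng.standard_normal((60, 4))
        # force the score column orthogonal to the SNP columns
        q_s = Q[:, -1] - Q[:, :-1] @ np.linalg.lstsq(Q[:, :-1], Q[:, -1], rcond=None)[0]
        Q[:, -1] = q_s
        comp = self._components_from_Q(Q)
        assert np.allclose(comp.C_RS, 0, atol=1e-8)
        red = eigen_reduce(comp.V_R, 1.0)
        res = jst_statistic(comp, red)
        U_R, U_S = comp.U[:-1], comp.U[-1]
        expected = U_R @ np.linalg.solve(comp.V_R, U_R) + U_S**2 / comp.V_S
        np.testing.assert_allclose(res.statistic, expected, atol=1e-8)

    @pytest.mark.parametrize("seed", [15, 16, 17])
    def test_full_rank_equals_hotelling_direct_inverse(self, seed):
        rng = np.random.default_rng(seed)
        Q = rng.standard_normal((80, 6))
        comp = self._components_from_Q(Q)
        red = eigen_reduce(comp.V_R, 1.0)
        assert red.s == 5
        res = jst_statistic(comp, red)
        hotelling = comp.U @ np.linalg.inv(comp.V_hat) @ comp.U
        np.testing.assert_allclose(res.statistic, hotelling, rtol=1e-8)
        assert res.df == 6

    def test_lambda_scaling_diagnostic_differs_when_truncated(self):
        rng = np.random.default_rng(18)
        Q = rng.standard_normal((80, 6)) * np.array([3, 2, 1, 1, 0.5, 1.0])
        comp = self._components_from_Q(Q)
        red = eigen_reduce(comp.V_R, 0.65)
        sqrt_res = jst_statistic(comp, red, scaling="sqrt")
        lam_res = jst_statistic(comp, red, scaling="lambda")
        assert sqrt_res.statistic != pytest.approx(lam_res.statistic)

    def test_degenerate_score_reduces_df(self):
        rng = np.random.default_rng(19)
        Q = rng.standard_normal((50, 4))
        Q[:, -1] = 0.0
        comp = self._components_from_Q(Q)
        red = eigen_reduce(comp.V_R, 1.0)
        res = jst_statistic(comp, red)
        assert res.score_degenerate and res.df == red.s


class TestJSTTest:
    def test_monomorphic_columns_dropped(self):
        cohort = _random_cohort(20)
        X = cohort.X.copy()
        X[:, 2] = 1.0
        c2 = PairedCohort(Y=cohort.Y, W=cohort.W, X=X, Z=cohort.Z)
        res = jst_test(c2, var_explained=0.85)
        assert res.n_snps_used == cohort.m - 1

    def test_statistic_invariant_to_column_rescaling_full_rank(self):
        cohort = _random_cohort(21)
        res1 = jst_test(cohort, var_explained=1.0)
        X2 = cohort.X.copy()
        X2[:, 0] *= 7.5
        res2 = jst_test(
            PairedCohort(Y=cohort.Y, W=cohort.W, X=X2, Z=cohort.Z), var_explained=1.0
        )
        np.testing.assert_allclose(res1.statistic, res2.statistic, rtol=1e-8)
        np.testing.assert_allclose(res1.p_value, res2.p_value, rtol=1e-8)

    def test_duplicating_pairs_preserves_fit_and_score_direction(self):
        cohort = _random_cohort(22)
        nf = fit_null(cohort.Y, cohort.W, "binary")
        Y2, W2 = np.tile(cohort.Y, 2), np.tile(cohort.W, (2, 1))
        nf2 = fit_null(Y2, W2, "binary")
        np.testing.assert_allclose(nf2.fitted_mean[: cohort.n], nf.fitted_mean, atol=1e-6)
        d1 = residualize(cohort.X, cohort.Z, cohort.W, nf.weights)
        d2 = residualize(np.tile(cohort.X, (2, 1)), np.tile(cohort.Z, 2), W2, nf2.weights)
        U1 = score_components(cohort.Y, nf, d1).U
        U2 = score_components(Y2, nf2, d2).U
        np.testing.assert_allclose(U2, 2 * U1, atol=1e-6)

    def test_continuous_outcome_end_to_end(self):
        cohort = _random_cohort(23, outcome="continuous")
        res = jst_test(cohort, var_explained=0.85)
        assert 0 <= res.p_value <= 1 and res.df == res.s + 1

    def test_permuting_outcome_gives_roughly_uniform_pvalues(self):
        """Permutation oracle: shuffling Y breaks any association."""
        cohort = _random_cohort(24, n=200)
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(200):
            Yp = rng.permutation(cohort.Y)
            c = PairedCohort(Y=Yp, W=cohort.W, X=cohort.X, Z=cohort.Z)
            pvals.append(jst_test(c, var_explained=0.85).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_no_usable_snps_fails(self):
        cohort = _random_cohort(25)
        X = np.ones_like(cohort.X)
        with pytest.raises(ValueError):
            jst_test(PairedCohort(Y=cohort.Y, W=cohort.W, X=X, Z=cohort.Z))


def test_cohort_invariants():
    with pytest.raises(ValueError):
        PairedCohort(Y=np.array([1.0, 2.0, 0.0]), W=np.empty((3, 0)),
                     X=np.zeros((3, 2)), Z=np.zeros(3), outcome_type="binary")
    with pytest.raises(ValueError):
        PairedCohort(Y=np.ones(4), W=np.empty((4, 0)),
                     X=np.zeros((4, 2)), Z=np.zeros(4), outcome_type="binary")
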