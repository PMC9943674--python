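import numpy as np
import pytest

from dragonet import (
    PairedOmicsData,
    RiskTerms,
    covariance_moments,
    monte_carlo_risk,
    risk,
    risk_terms,
    select_lambda_diagonal,
    select_lambdas,
    standardize,
)
from dragonet.simulate import StudyConfig, generate_precision


def loop_moments(A, B):
    """Triple-loop oracle for the covariance-entry moments."""
    n = A.shape[0]
    pa, pb = A.shape[1], B.shape[1]
    var = np.zeros((pa, pb))
    esq = np.zeros((pa, pb))
    for i in range(pa):
        for j in range(pb):
            w = np.array(
                [(A[m, i] - A[:, i].mean()) * (B[m, j] - B[:, j].mean()) for m in range(n)]
            )
            wbar = w.mean()
            s = n / (n - 1) * wbar
            var[i, j] = n / (n - 1) ** 3 * ((w - wbar) ** 2).sum()
            esq[i, j] = s * s
    return var, esq


class TestCovarianceMoments:
    def test_matches_triple_loop_oracle(self, small_data):
        m = covariance_moments(small_data, scale=True)
        X1 = standardize(small_data.X1)
        X2 = standardize(small_data.X2)
        for (var, esq), (A, B) in [
            ((m.var_s11, m.esq_s11), (X1, X1)),
            ((m.var_s22, m.esq_s22), (X2, X2)),
            ((m.var_s12, m.esq_s12), (X1, X2)),
        ]:
            var_o, esq_o = loop_moments(A, B)
            np.testing.assert_allclose(var, var_o, atol=1e-12)
            np.testing.assert_allclose(esq, esq_o, atol=1e-12)

    def test_constant_feature_pair_has_zero_variance(self, rng):
        X1 = rng.standard_normal((6, 2))
        X1[:, 1] = 5.0  # constant: every w_mij is zero
        data = PairedOmicsData(X1=X1, X2=rng.standard_normal((6, 2)), validate=False)
        m = covariance_moments(data, scale=False)
        assert np.all(m.var_s11[1, :] == 0)
        np.testing.assert_allclose(m.esq_s11[1, 0], 0.0, atol=1e-30)

    def test_duplicated_feature_symmetry(self, rng):
        x = rng.standard_normal(10)
        data = PairedOmicsData(
            X1=np.column_stack([x, x]), X2=rng.standard_normal((10, 1)), validate=False
        )
        m = covariance_moments(data, scale=False)
        # var(s_xy) with y = x equals var(s_xx)
        np.testing.assert_allclose(m.var_s11[0, 1], m.var_s11[0, 0], atol=1e-12)

    def test_too_few_samples_rejected(self, rng):
        data = PairedOmicsData(
            X1=rng.standard_normal((2, 2)), X2=rng.standard_normal((2, 2)), validate=False
        )
        with pytest.raises(ValueError, match="at least 3"):
            covariance_moments(data)


class TestRiskTerms:
    def test_matches_direct_summation(self, small_data):
        m = covariance_moments(small_data)
        t = risk_terms(m)
        off = lambda M: M.sum() - np.trace(M)
        assert t.t1_1 == pytest.approx(-2 * (off(m.var_s11) + m.esq_s12.sum()))
        assert t.t1_2 == pytest.approx(-2 * (off(m.var_s22) + m.esq_s12.sum()))
        assert t.t2_1 == pytest.approx(off(m.esq_s11))
        assert t.t2_2 == pytest.approx(off(m.esq_s22))
        assert t.t3 == pytest.approx(2 * m.esq_s12.sum())
        assert t.t4 == pytest.approx(4 * (m.var_s12.sum() - m.esq_s12.sum()))

    def test_single_feature_layers(self, rng):
        data = PairedOmicsData(
            X1=rng.standard_normal((12, 1)), X2=rng.standard_normal((12, 1))
        )
        t = risk_terms(covariance_moments(data))
        assert t.t2_1 == 0.0 and t.t2_2 == 0.0  # no off-diagonal within-layer pairs
        m = covariance_moments(data)
        assert t.t3 == pytest.approx(2 * m.esq_s12[0, 0])


class TestRisk:
    terms = RiskTerms(t1_1=-2.0, t1_2=-1.0, t2_1=1.5, t2_2=2.0, t3=0.8, t4=-3.0)

    def test_corner_values(self):
        assert risk(0, 0, self.terms) == pytest.approx(self.terms.t4)
        expected = -2.0 - 1.0 + 1.5 + 2.0 + 0.8
        assert risk(1, 1, self.terms) == pytest.approx(expected)

    def test_hand_evaluation(self):
        l1, l2 = 0.5, 0.25
        expected = (
            l1 * -2.0 + l2 * -1.0 + l1**2 * 1.5 + l2**2 * 2.0
            + l1 * l2 * 0.8 + np.sqrt(0.5) * np.sqrt(0.75) * -3.0
        )
        assert risk(l1, l2, self.terms) == pytest.approx(expected, abs=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            risk(1.2, 0.5, self.terms)


class TestSelectLambdas:
    def test_separable_quadratic_closed_form(self):
        terms = RiskTerms(t1_1=-1.2, t1_2=-3.0, t2_1=1.0, t2_2=1.0, t3=0.0, t4=0.0)
        est = select_lambdas(terms)
        assert est.lambda1 == pytest.approx(min(1.2 / 2, 1.0), abs=1e-6)
        assert est.lambda2 == pytest.approx(1.0, abs=1e-6)  # clipped at the boundary

    def test_nondecreasing_risk_gives_zero(self):
        terms = RiskTerms(t1_1=1.0, t1_2=0.5, t2_1=1.0, t2_2=1.0, t3=0.2, t4=0.0)
        est = select_lambdas(terms)
        assert est.lambda1 == pytest.approx(0.0, abs=1e-9)
        assert est.lambda2 == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_dense_grid(self, seed):
        r = np.random.default_rng(seed)
        terms = RiskTerms(
            t1_1=r.normal(scale=2),
            t1_2=r.normal(scale=2),
            t2_1=abs(r.normal()) + 0.1,
            t2_2=abs(r.normal()) + 0.1,
            t3=abs(r.normal()),
            t4=r.normal(scale=2),
        )
        est = select_lambdas(terms)
        g = np.linspace(0, 1, 1001)
        L1, L2 = np.meshgrid(g, g, indexing="ij")
        R = risk(L1, L2, terms)
        i, j = np.unravel_index(np.argmin(R), R.shape)
        assert abs(est.lambda1 - g[i]) < 1e-3
        assert abs(est.lambda2 - g[j]) < 1e-3
        assert est.risk_value <= R.min() + 1e-12

    def test_non_finite_terms_rejected(self):
        terms = RiskTerms(np.nan, 0, 1, 1, 0, 0)
        with pytest.raises(ValueError):
            select_lambdas(terms)


class TestSelectLambdaDiagonal:
    def test_symmetric_terms_match_unconstrained(self):
        terms = RiskTerms(t1_1=-2.0, t1_2=-2.0, t2_1=1.4, t2_2=1.4, t3=0.5, t4=-0.3)
        con = select_lambda_diagonal(terms)
        unc = select_lambdas(terms)
        assert con.lambda1 == con.lambda2
        assert con.risk_value == pytest.approx(unc.risk_value, abs=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_constrained_at_least_unconstrained(self, seed):
        r = np.random.default_rng(100 + seed)
        terms = RiskTerms(
            r.normal(scale=2), r.normal(scale=2),
            abs(r.normal()) + 0.1, abs(r.normal()) + 0.1,
            abs(r.normal()), r.normal(scale=2),
        )
        con = select_lambda_diagonal(terms)
        unc = select_lambdas(terms)
        assert con.constrained
        assert con.risk_value >= unc.risk_value - 1e-10
        # 1-D dense grid oracle
        g = np.linspace(0, 1, 5001)
        vals = risk(g, g, terms)
        assert abs(con.lambda1 - g[np.argmin(vals)]) < 1e-3

    def test_classical_single_penalty_formula(self, small_data):
        """On the diagonal the optimum is sum(var)/sum(s^2) over all
        off-diagonal entries of the appended covariance (clipped to [0,1])."""
        m = covariance_moments(small_data)
        t = risk_terms(m)
        est = select_lambda_diagonal(t)
        off = lambda M: M.sum() - np.trace(M)
        num = off(m.var_s11) + off(m.var_s22) + 2 * m.var_s12.sum()
        den = off(m.esq_s11) + off(m.esq_s22) + 2 * m.esq_s12.sum()
        assert est.lambda1 == pytest.approx(min(1.0, num / den), abs=1e-6)


class TestMonteCarloRisk:
    def test_deterministic_under_seed(self):
        sigma = np.array([[1.0, 0.3], [0.3, 1.0]])
        grid = np.linspace(0, 1, 5)
        a = monte_carlo_risk(sigma, 1, grid, grid, n=30, reps=10, seed=42)
        b = monte_carlo_risk(sigma, 1, grid, grid, n=30, reps=10, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_full_shrinkage_limit(self, rng):
        """At lambda1 = lambda2 = 1 the estimator keeps only the sample
        diagonal, so the risk concentrates near ||T - Sigma||_F^2."""
        sigma = np.array([[2.0, 0.8, 0.1], [0.8, 1.0, 0.2], [0.1, 0.2, 1.5]])
        val = monte_carlo_risk(sigma, 1, np.array([1.0]), np.array([1.0]),
                               n=20000, reps=3, seed=0)[0, 0]
        off = sigma - np.diag(np.diag(sigma))
        assert val == pytest.approx((off**2).sum(), rel=0.05)

    def test_argmin_matches_analytic_risk(self):
        """The mean analytic risk surface localizes the same optimum as the
        Monte-Carlo ground truth on a small two-layer instance."""
        config = StudyConfig(p1=10, p2=20, density=(0.05, 0.05, 0.05), noise_sd=0.0)
        truth = generate_precision(config, seed=5)
        sigma = np.linalg.inv(truth.theta)
        d = 1.0 / np.sqrt(np.diag(sigma))
        sigma_star = sigma * d[:, None] * d[None, :]
        n, reps = 400, 60
        grid = np.linspace(0, 1, 26)
        surface = monte_carlo_risk(sigma_star, 10, grid, grid, n=n, reps=reps, seed=11)
        i, j = np.unravel_index(np.argmin(surface), surface.shape)

        L1, L2 = np.meshgrid(grid, grid, indexing="ij")
        acc = np.zeros_like(L1)
        r = np.random.default_rng(12)
        chol = np.linalg.cholesky(sigma_star)
        for _ in range(reps):
            X = r.standard_normal((n, 30)) @ chol.T
            data = PairedOmicsData(X1=X[:, :10], X2=X[:, 10:], validate=False)
            acc += risk(L1, L2, risk_terms(covariance_moments(data, scale=False)))
        ii, jj = np.unravel_index(np.argmin(acc), acc.shape)
        step = grid[1] - grid[0]
        assert abs(grid[ii] - grid[i]) <= step
        assert abs(grid[jj] - grid[j]) <= step

    def test_non_pd_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            monte_carlo_risk(np.array([[1.0, 2.0], [2.0, 1.0]]), 1,
                             np.array([0.5]), np.array([0.5]), n=10, reps=1, seed=0)


def test_lambdas_shrink_with_sample_size():
    """With p fixed, selected penalties decrease as n grows."""
    config = StudyConfig(p1=15, p2=30, density=(0.08, 0.05, 0.05), noise_sd=0.0)
    truth = generate_precision(config, seed=3)
    from dragonet.simulate import sample_dataset

    lams = []
    for n in (60, 240, 2000):
        data = sample_dataset(truth, n, seed=4)
        est = select_lambdas(risk_terms(covariance_moments(data)))
        lams.append(est.lambda1 + est.lambda2)
    assert lams[0] > lams[1] > lams[2]
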