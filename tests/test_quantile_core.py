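"""Unit and property tests for the quantile-regression kernels."""

import numpy as np
import pytest
from scipy import stats

from quantqtl.quantile_core import (
    QuantileGrid,
    cauchy_combine,
    chatterjee_xi,
    check_loss,
    fit_check_loss,
    fit_quantile_joint,
    fit_quantile_null,
    rank_score_scan,
    rank_score_test,
)


class TestCheckLossSolver:
    def test_median_intercept_only(self):
        fit = fit_quantile_null(np.array([1.0, 2, 3, 4, 5]), None, 0.5)
        assert fit.alpha0 == 3.0

    def test_lower_order_statistic_convention(self):
        # n*tau integer: the minimizer set is an interval; the lower order
        # statistic is returned. Verified against a brute-force grid below.
        y = np.arange(1.0, 9.0)
        fit = fit_quantile_null(y, None, 0.25)
        assert fit.alpha0 == 2.0
        grid = np.linspace(0, 10, 2001)
        losses = [check_loss(y - g, 0.25) for g in grid]
        assert fit.check_loss <= min(losses) + 1e-12

    def test_binary_covariate_gives_group_medians(self):
        y = np.array([1.0, 2, 3, 10, 11, 12])
        c = np.array([0.0, 0, 0, 1, 1, 1])
        fit = fit_quantile_null(y, c[:, None], 0.5)
        fitted = np.unique(np.round(fit.fitted, 9))
        assert set(fitted) == {2.0, 11.0}

    @pytest.mark.parametrize("tau", [0.05, 0.25, 0.5, 0.9])
    def test_interior_point_matches_lp_oracle(self, rng, tau):
        # the LP solution via HiGHS is the independent exact reference
        n, q = 120, 6
        X = np.column_stack([np.ones(n), rng.normal(size=(n, q))])
        y = rng.normal(size=n)
        _, loss_fn, _ = fit_check_loss(X, y, tau, solver="fn")
        _, loss_lp, _ = fit_check_loss(X, y, tau, solver="highs")
        assert loss_fn == pytest.approx(loss_lp, abs=1e-6)
        assert loss_fn >= loss_lp - 1e-9  # LP is the certified minimum

    def test_rank_deficient_design_raises(self, rng):
        n = 50
        c = rng.normal(size=n)
        X = np.column_stack([np.ones(n), c, c])
        with pytest.raises(np.linalg.LinAlgError):
            fit_check_loss(X, rng.normal(size=n), 0.5)

    def test_rank_scores_orthogonal_to_design(self, rng):
        n, q = 300, 20
        C = rng.normal(size=(n, q))
        fit = fit_quantile_null(rng.normal(size=n), C, 0.1)
        X = np.column_stack([np.ones(n), C])
        assert np.abs(X.T @ fit.rank_scores).max() < 1e-5
        assert fit.rank_scores.min() >= 0.1 - 1 - 1e-8
        assert fit.rank_scores.max() <= 0.1 + 1e-8


class TestRankScore:
    def test_constant_dosage_untestable(self):
        y = np.arange(10.0)
        fit = fit_quantile_null(y, None, 0.5)
        S, sigma, p = rank_score_test(np.ones(10), fit, None)
        assert np.isnan(S) and np.isnan(p) and sigma == 0.0

    def test_six_sample_oracle(self):
        # direct evaluation of the score formula with the solver's median
        Y = np.array([1.0, 2, 3, 4, 5, 6])
        G = np.array([0.0, 0, 1, 1, 2, 2])
        fit = fit_quantile_null(Y, None, 0.5)
        S, sigma, p = rank_score_test(G, fit, None)
        g_star = G - G.mean()
        resid = Y - 3.0
        phi = 0.5 - (resid < 0)
        phi[resid == 0] = -phi[resid != 0].sum()  # balancing score at the tie
        expected = g_star @ phi / np.sqrt(6)
        assert S == pytest.approx(expected, abs=1e-12)
        assert sigma**2 == pytest.approx(0.25 * g_star @ g_star / 6, abs=1e-15)

    def test_projection_invariance(self, rng):
        # adding any covariate-span vector to G leaves (S, p) unchanged
        n, q = 200, 4
        C = rng.normal(size=(n, q))
        Y = rng.normal(size=n)
        G = rng.binomial(2, 0.3, n).astype(float)
        fit = fit_quantile_null(Y, C, 0.3)
        S1, _, p1 = rank_score_test(G, fit, C)
        shift = 3.0 * C[:, 1] - 0.7 + 0.1 * C[:, 3]
        S2, _, p2 = rank_score_test(G + shift, fit, C)
        assert S1 == pytest.approx(S2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_sigma_identity(self, rng):
        n = 150
        C = rng.normal(size=(n, 3))
        fit = fit_quantile_null(rng.normal(size=n), C, 0.2)
        G = rng.binomial(2, 0.2, n).astype(float)
        scan = rank_score_scan(G[:, None], [fit], C)
        tau = 0.2
        assert scan.sigma[0, 0] ** 2 == pytest.approx(
            tau * (1 - tau) * scan.gstar_norm2[0] / n, rel=0, abs=1e-15
        )

    def test_null_pvalues_uniform(self, rng):
        # per-level rank-score p-values are uniform under the null; the
        # Cauchy-combined p of dependent levels is calibrated in the tail
        n = 400
        C = rng.normal(size=(n, 5))
        grid = QuantileGrid.mapping()
        per_tau, combined = [], []
        for _ in range(4):
            Y = rng.normal(size=n)
            fits = [fit_quantile_null(Y, C, float(t)) for t in grid]
            G = rng.binomial(2, 0.25, size=(n, 500)).astype(float)
            scan = rank_score_scan(G, fits, C)
            per_tau.extend(scan.pvalues[9, :].tolist())  # tau = 0.5
            combined.extend(scan.combined_p.tolist())
        assert stats.kstest(per_tau, "uniform").pvalue > 0.001
        combined = np.asarray(combined)
        assert 0.035 <= (combined < 0.05).mean() <= 0.065


class TestCauchyCombine:
    def test_equal_inputs_fixed_point(self):
        assert cauchy_combine([0.05] * 7) == pytest.approx(0.05, abs=1e-12)

    def test_single_identity(self):
        assert cauchy_combine([0.3]) == pytest.approx(0.3, abs=1e-12)

    def test_two_values_direct_transform(self):
        t = 0.5 * (np.tan((0.5 - 0.01) * np.pi) + np.tan((0.5 - 0.5) * np.pi))
        expected = 0.5 - np.arctan(t) / np.pi
        assert cauchy_combine([0.01, 0.5]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0200, abs=5e-4)

    def test_monotonicity(self, rng):
        for _ in range(50):
            p = rng.uniform(0.001, 0.999, size=5)
            base = cauchy_combine(p)
            k = rng.integers(0, 5)
            p2 = p.copy()
            p2[k] = p[k] * rng.uniform(0.1, 0.99)
            assert cauchy_combine(p2) <= base + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cauchy_combine([])

    def test_extreme_inputs_clipped_not_overflowing(self):
        out = cauchy_combine([1e-300, 0.9999999999999999])
        assert 0.0 < out < 1.0


class TestChatterjee:
    def test_monotone_increasing(self):
        xi, p = chatterjee_xi(np.arange(9.0), np.arange(9.0))
        assert xi == pytest.approx(0.7, abs=1e-12)
        assert p < 0.05

    def test_sign_blind(self):
        xi, _ = chatterjee_xi(np.arange(9.0), -np.arange(9.0))
        assert xi == pytest.approx(0.7, abs=1e-12)

    def test_independent_near_zero(self, rng):
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        xi, _ = chatterjee_xi(x, y)
        assert abs(xi) < 0.05

    def test_all_equal_y(self):
        xi, p = chatterjee_xi(np.arange(5.0), np.ones(5))
        assert xi == 0.0 and p == 1.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            chatterjee_xi([1, 2], [1, 2])


class TestJointFit:
    def test_collinear_with_covariate_raises(self, rng):
        n = 80
        c = rng.normal(size=n)
        with pytest.raises(np.linalg.LinAlgError):
            fit_quantile_joint(rng.normal(size=n), c[:, None], c[:, None],
                               [0.5])

    def test_single_level_consistent_with_null_fit(self, rng):
        n = 150
        C = rng.normal(size=(n, 2))
        G = rng.binomial(2, 0.3, n).astype(float)
        Y = 0.4 * G + C @ [0.2, -0.1] + rng.normal(size=n)
        betas = fit_quantile_joint(Y, G[:, None], C, [0.5])
        assert betas.shape == (1, 1)
        # the same fit through the generic solver path
        X = np.column_stack([np.ones(n), C, G])
        coef, _, _ = fit_check_loss(X, Y, 0.5)
        assert betas[0, 0] == pytest.approx(coef[-1], abs=1e-6)

    def test_scale_model_slopes_follow_closed_form(self, rng):
        # Y = (1 + s G) eps: quantile slope in tau is s * qnorm(tau) * sd(eps)
        n, s = 4000, 0.5
        G = rng.binomial(2, 0.3, n).astype(float)
        Y = (1 + s * G) * rng.normal(size=n)
        taus = np.array([0.1, 0.25, 0.5, 0.75, 0.9])
        betas = fit_quantile_joint(Y, G[:, None], None, taus)[0]
        expected = s * stats.norm.ppf(taus)
        assert np.max(np.abs(betas - expected)) < 0.12
        assert betas[0] < 0 < betas[-1]
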