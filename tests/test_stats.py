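"""Statistical layer: OLS/AIC, forward selection, Welch ANOVA, Games-Howell,
effect sizes, correlations, logistic classification.  Oracles: closed-form
identities, brute-force normal equations, numerical integration of the
studentized-range distribution, and pingouin/statsmodels cross-checks."""

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

from lungpatterns.stats import (aic_ols, auc_mann_whitney, cohens_d, correlation,
                                forward_select, games_howell, logistic_eval, ols_fit,
                                roc_curve_points, welch_anova)


class TestOLS:
    def test_exact_linear_relation(self, rng):
        x = rng.standard_normal((30, 2))
        y = 3.0 + 2.0 * x[:, 0] - x[:, 1]
        fit = ols_fit(x, y)
        assert fit.rss == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_response_gives_zero_slopes(self):
        x = np.linspace(-1, 1, 21)[:, None]
        y = np.full(21, 5.0)
        fit = ols_fit(x, y)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.standard_normal((50, 3))
        y = rng.standard_normal(50)
        fit = ols_fit(x, y)
        design = np.column_stack([np.ones(50), x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.standard_normal((40, 2))
        y = x @ [1.0, -2.0] + rng.standard_normal(40)
        fit = ols_fit(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-10)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-10)

    def test_collinear_columns_named(self, rng):
        x = rng.standard_normal((20, 2))
        x = np.column_stack([x, x[:, 0] * 2.0])
        with pytest.raises(ValueError, match="collinear"):
            ols_fit(x, rng.standard_normal(20))


class TestAIC:
    def test_ln_one_case(self):
        from lungpatterns.stats import OLSFit

        fit = OLSFit(coefficients=np.zeros(2), rss=10.0, r2=0.5, n=10, k=1)
        assert aic_ols(fit) == pytest.approx(6.0)

    def test_extra_parameter_costs_exactly_two(self):
        from lungpatterns.stats import OLSFit

        a = OLSFit(coefficients=np.zeros(2), rss=7.3, r2=0.5, n=25, k=1)
        b = OLSFit(coefficients=np.zeros(3), rss=7.3, r2=0.5, n=25, k=2)
        assert aic_ols(b) - aic_ols(a) == pytest.approx(2.0)

    def test_monotone_in_rss(self):
        from lungpatterns.stats import OLSFit

        fits = [OLSFit(coefficients=np.zeros(2), rss=r, r2=0.0, n=30, k=1)
                for r in (5.0, 4.0, 1.0)]
        aics = [aic_ols(f) for f in fits]
        assert aics[0] > aics[1] > aics[2]

    def test_zero_rss_warns_negative_infinity(self):
        from lungpatterns.stats import OLSFit

        with pytest.warns(UserWarning):
            assert aic_ols(OLSFit(np.zeros(2), 0.0, 1.0, 10, 1)) == -np.inf

    def test_model_recovery_on_simulated_subsets(self):
        # The AIC-minimal subset over all 2^6 candidates always contains the
        # true 2-of-6 predictors; it equals them exactly only when no noise
        # variable clears AIC's implicit chi^2 > 2 inclusion bar (probability
        # ~0.843 per noise variable, so ~0.5 for the exact set).
        import itertools

        gen = np.random.default_rng(0)
        exact, superset = 0, 0
        for _ in range(50):
            x = gen.standard_normal((200, 6))
            y = 1.2 * x[:, 0] - 0.9 * x[:, 1] + gen.standard_normal(200)
            best, best_aic = None, np.inf
            for r in range(7):
                for sub in itertools.combinations(range(6), r):
                    a = aic_ols(ols_fit(x[:, list(sub)], y))
                    if a < best_aic:
                        best_aic, best = a, set(sub)
            exact += best == {0, 1}
            superset += {0, 1} <= best
        assert superset == 50
        assert exact >= 20


class TestForwardSelect:
    def test_perfect_predictor_selected_alone(self, rng):
        x = rng.standard_normal((100, 6))
        y = x[:, 1].copy()
        selected, fit = forward_select(x, y)
        assert selected == [1]
        assert fit.r2 == pytest.approx(1.0)

    def test_null_selection_mostly_empty(self):
        # with m noise candidates the selection ends empty with probability
        # ~0.95^m under the per-step alpha=0.05 stop rule; two candidates keep
        # that above 90%
        gen = np.random.default_rng(1)
        empty = sum(not forward_select(gen.standard_normal((200, 2)),
                                       gen.standard_normal(200))[0]
                    for _ in range(50))
        assert empty >= 45

    def test_r2_sequence_nondecreasing(self, rng):
        x = rng.standard_normal((120, 5))
        y = x @ [1.0, 0.5, 0.0, 0.0, 0.3] + 0.5 * rng.standard_normal(120)
        selected, _ = forward_select(x, y)
        r2s = [ols_fit(x[:, selected[:i + 1]], y).r2 for i in range(len(selected))]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_recovers_planted_predictors_on_strong_signals(self):
        from lungpatterns.experiments import forward_selection_rates

        rates = forward_selection_rates(seed=2, n_reps=25)
        assert rates["planted_truth_rate"] >= 0.8
        # the alpha=0.05 stop is stricter than AIC's implicit inclusion bar,
        # so agreement with the exhaustive best-AIC subset is lower
        assert rates["planted_match_rate"] >= 0.5
        assert rates["null_empty_rate"] >= 0.85


class TestWelchAnova:
    def test_identical_groups_give_zero_f(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = welch_anova([g, list(g)])
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_equal_squared_welch_t(self, rng):
        a = rng.normal(0, 1, 18)
        b = rng.normal(1, 2.5, 25)
        res = welch_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=False)
        assert res.f_stat == pytest.approx(t.statistic ** 2, abs=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, abs=1e-10)

    def test_textbook_formula_oracle_three_groups(self):
        groups = [np.array([2.1, 2.8, 3.0, 3.4, 2.2]),
                  np.array([4.9, 5.3, 6.1, 4.4, 5.8, 6.0]),
                  np.array([1.0, 3.5, 2.0, 4.5])]
        res = welch_anova(groups)
        # independent textbook computation
        n = np.array([len(g) for g in groups], float)
        m = np.array([g.mean() for g in groups])
        v = np.array([g.var(ddof=1) for g in groups])
        w = n / v
        mw = (w * m).sum() / w.sum()
        k = 3
        num = (w * (m - mw) ** 2).sum() / (k - 1)
        tmp = (((1 - w / w.sum()) ** 2) / (n - 1)).sum()
        f = num / (1 + 2 * (k - 2) / (k ** 2 - 1) * tmp)
        df2 = (k ** 2 - 1) / (3 * tmp)
        assert res.f_stat == pytest.approx(f, abs=1e-10)
        assert res.df2 == pytest.approx(df2, abs=1e-10)
        assert res.p_value == pytest.approx(sps.f.sf(f, 2, df2), abs=1e-12)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        groups = [rng.normal(0, 1, 15), rng.normal(0.8, 2, 20), rng.normal(-0.5, 0.7, 12)]
        res = welch_anova(groups)
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat([0, 1, 2], [15, 20, 12]),
        })
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert res.f_stat == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_reduces_to_classic_anova_for_equal_variances(self):
        # k = 2 with equal variances and sizes: Welch F equals classic F
        # exactly (the k >= 3 correction factor b vanishes at k = 2)
        gen = np.random.default_rng(2)
        base = gen.normal(0, 1, 20)
        two = [base + 0.0, gen.permutation(base) + 0.5]
        res = welch_anova(two)
        classic = sps.f_oneway(*two)
        assert res.f_stat == pytest.approx(classic.statistic, abs=1e-6)
        # k = 3: Welch F times its variance-heterogeneity correction factor b
        # recovers classic F when group variances and sizes are equal
        three = [base, gen.permutation(base) + 0.5, gen.permutation(base) + 1.0]
        res3 = welch_anova(three)
        n = np.full(3, 20.0)
        w = n / np.array([g.var(ddof=1) for g in three])
        tmp = (((1 - w / w.sum()) ** 2) / (n - 1)).sum()
        b = 1 + 2 * (3 - 2) / (3 ** 2 - 1) * tmp
        assert res3.f_stat * b == pytest.approx(sps.f_oneway(*three).statistic,
                                                rel=1e-10)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            welch_anova([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])


def studentized_range_sf_oracle(q, k, df):
    """Numerical integration of the studentized range survival function,
    independent of scipy.stats.studentized_range."""

    def cdf_given_s(s):
        def inner(z):
            return sps.norm.pdf(z) * (sps.norm.cdf(z) - sps.norm.cdf(z - q * s)) ** (k - 1)

        val, _ = integrate.quad(inner, -8, 8, limit=200)
        return k * val

    def integrand(s):
        # density of s = chi_df / sqrt(df)
        from scipy.special import gammaln

        log_pdf = (np.log(2) + (df / 2) * np.log(df / 2) - gammaln(df / 2)
                   + (df - 1) * np.log(s) - df * s * s / 2)
        return np.exp(log_pdf) * cdf_given_s(s)

    val, _ = integrate.quad(integrand, 1e-6, 5, limit=200)
    return 1.0 - val


class TestGamesHowell:
    def test_identical_groups_give_p_near_one(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        for comp in games_howell([g, list(g), list(g)]):
            assert comp.p_value >= 0.999

    def test_reordering_flips_sign_keeps_p(self, rng):
        groups = [rng.normal(0, 1, 10), rng.normal(1, 2, 12), rng.normal(2, 1, 9)]
        a = games_howell(groups, labels=["x", "y", "z"])
        b = games_howell(groups[::-1], labels=["z", "y", "x"])
        pa = {frozenset((c.group_a, c.group_b)): c for c in a}
        pb = {frozenset((c.group_a, c.group_b)): c for c in b}
        for key in pa:
            assert pa[key].p_value == pytest.approx(pb[key].p_value, abs=1e-12)
            assert abs(pa[key].mean_diff) == pytest.approx(abs(pb[key].mean_diff))

    def test_critical_value_and_p_against_integration_oracle(self):
        # published critical value: q(alpha=0.05, k=3, df=10) = 3.88
        q_crit = sps.studentized_range.isf(0.05, 3, 10)
        assert q_crit == pytest.approx(3.88, abs=0.01)
        assert studentized_range_sf_oracle(q_crit, 3, 10) == pytest.approx(0.05,
                                                                           abs=1e-4)
        gen = np.random.default_rng(3)
        groups = [gen.normal(0, 1, 8), gen.normal(1.2, 2, 6), gen.normal(0.3, 0.6, 7)]
        for comp in games_howell(groups):
            want = studentized_range_sf_oracle(comp.q_stat, 3, comp.df)
            assert comp.p_value == pytest.approx(want, abs=1e-4)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        groups = [rng.normal(0, 1, 11), rng.normal(1, 2, 14), rng.normal(-1, 0.5, 9)]
        ours = games_howell(groups, labels=[0, 1, 2])
        df = pd.DataFrame({"y": np.concatenate(groups),
                           "g": np.repeat([0, 1, 2], [11, 14, 9])})
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        ref_p = {frozenset((int(r.A), int(r.B))): float(r.pval)
                 for r in ref.itertuples()}
        for comp in ours:
            assert comp.p_value == pytest.approx(
                ref_p[frozenset((comp.group_a, comp.group_b))], abs=1e-6)


class TestCohensD:
    def test_identical_samples_zero(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])  # zero pooled sd
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_one_pooled_sd_shift(self, rng):
        a = rng.normal(0, 1, 10)
        pooled = np.sqrt(a.var(ddof=1))  # same sample shifted: pooled sd = sd(a)
        b = a + pooled
        assert abs(cohens_d(a, b)) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed(self):
        a = np.arange(10.0)
        b = np.arange(10.0) + 3.0
        sp = np.sqrt(((9 * a.var(ddof=1)) + 9 * b.var(ddof=1)) / 18)
        assert cohens_d(a, b) == pytest.approx(-3.0 / sp)


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.kind == "pearson"

    def test_binary_flagged_and_equals_pearson(self, rng):
        x = (rng.random(50) < 0.5).astype(float)
        y = rng.standard_normal(50)
        res = correlation(x, y)
        assert res.kind == "point_biserial"
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == r_ref
        assert res.p_value == p_ref

    def test_null_binary_correlation_small(self):
        gen = np.random.default_rng(4)
        x = np.repeat([0.0, 1.0], 500)
        y = gen.standard_normal(1000)  # group means equal by construction
        res = correlation(x, y)
        assert abs(res.r) < 4 / np.sqrt(1000)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLogisticEval:
    def test_perfect_separation_auc_one(self):
        x = np.concatenate([np.zeros(20) - 2, np.zeros(20) + 2])
        y = np.concatenate([np.zeros(20), np.ones(20)])
        with pytest.warns(UserWarning, match="separation"):
            _, ev = logistic_eval(x, y)
        assert ev.auc == 1.0
        assert ev.accuracy == 1.0
        assert ev.separated

    def test_null_auc_near_half(self):
        gen = np.random.default_rng(5)
        x = gen.standard_normal(2000)
        y = (gen.random(2000) < 0.5).astype(float)
        _, ev = logistic_eval(x, y)
        n1 = y.sum()
        n0 = 2000 - n1
        se = np.sqrt((n0 + n1 + 1) / (12 * n0 * n1))
        assert abs(ev.auc - 0.5) < 4 * se

    def test_label_flip_maps_auc(self, rng):
        x = rng.standard_normal((300, 2))
        y = (x[:, 0] + 0.5 * rng.standard_normal(300) > 0).astype(float)
        _, ev = logistic_eval(x, y)
        auc_flipped = auc_mann_whitney(
            np.asarray([row @ [1.0, 0.0] for row in x]), (1 - y).astype(int))
        # flipping labels on the same scores mirrors the rank AUC exactly
        scores = x[:, 0]
        assert (auc_mann_whitney(scores, y.astype(int))
                + auc_mann_whitney(scores, (1 - y).astype(int))) == pytest.approx(1.0)

    def test_rank_auc_equals_trapezoidal_roc(self, rng):
        scores = rng.standard_normal(500)
        scores[::7] = scores[0]  # inject ties
        labels = (rng.random(500) < 0.4).astype(int)
        auc = auc_mann_whitney(scores, labels)
        pts = roc_curve_points(scores, labels)
        trap = np.trapezoid(pts[:, 1], pts[:, 0])
        assert auc == pytest.approx(trap, abs=1e-12)

    def test_coefficients_match_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.standard_normal((400, 2))
        lin = 0.5 + x @ [1.0, -0.7]
        y = (rng.random(400) < 1 / (1 + np.exp(-lin))).astype(float)
        coef, ev = logistic_eval(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(coef, ref.params, atol=1e-6)

    def test_confusion_matrix_consistency(self, rng):
        x = rng.standard_normal(200)
        y = (rng.random(200) < 0.5).astype(float)
        _, ev = logistic_eval(x, y)
        assert ev.confusion.sum() == 200
        tn, fp = ev.confusion[0]
        fn, tp = ev.confusion[1]
        assert ev.accuracy == pytest.approx((tn + tp) / 200)
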