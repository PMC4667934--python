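import itertools
import math

import numpy as np
import pytest
from lifelines.statistics import logrank_test
from scipy.optimize import minimize

from igvprog.survival_stats import (
    bh_fdr,
    binarize_covariates,
    cox_log_partial_likelihood,
    cox_partial_likelihood,
    fit_elastic_net_cox,
    multivariate_cox,
    select_alpha,
    strata_labels,
    stratified_mh_test,
    univariate_cox,
)


def simulate_cohort(n, beta, seed, censor_scale=2.0, p=1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    lp = X @ (np.full(p, beta) if np.isscalar(beta) else np.asarray(beta))
    t = rng.exponential(np.exp(-lp))
    c = rng.exponential(censor_scale, n)
    return X, np.minimum(t, c) + 1e-9, t <= c


class TestPartialLikelihood:
    def test_null_coefficients_all_events_gives_inverse_factorial(self):
        n = 6
        times = np.arange(1.0, n + 1)
        X = np.random.default_rng(0).normal(size=(n, 2))
        L = cox_partial_likelihood(np.zeros(2), X, times, np.ones(n, bool))
        assert L == pytest.approx(1.0 / math.factorial(n), rel=1e-12)

    def test_two_subject_hand_value(self):
        # subject 1 (x=1) dies first, subject 2 (x=0) later, theta=1:
        # factor1 = e/(e+1), factor2 = 1
        L = cox_partial_likelihood([1.0], np.array([[1.0], [0.0]]),
                                   [1.0, 2.0], [True, True])
        assert L == pytest.approx(np.e / (np.e + 1.0), rel=1e-12)

    def test_censored_subject_enters_risk_sets_only(self):
        X = np.array([[0.5], [-0.2], [0.9]])
        times = np.array([1.0, 2.0, 3.0])
        theta = np.array([0.7])
        eta = (X @ theta).ravel()

        def brute(events):
            L = 1.0
            for j in range(3):
                if not events[j]:
                    continue
                risk = [jj for jj in range(3) if times[jj] >= times[j]]
                L *= np.exp(eta[j]) / sum(np.exp(eta[r]) for r in risk)
            return L

        with_event = (True, True, True)
        censored_mid = (True, False, True)
        for events in (with_event, censored_mid):
            got = cox_partial_likelihood(theta, X, times, list(events))
            assert got == pytest.approx(brute(events), rel=1e-12)
        assert brute(with_event) != pytest.approx(brute(censored_mid))

    def test_matches_hand_expanded_product_small_n(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = rng.integers(2, 6)
            X = rng.normal(size=(n, 2))
            theta = rng.normal(size=2)
            times = rng.choice(np.arange(1.0, 4.0), size=n)  # includes ties
            events = rng.random(n) < 0.7
            eta = X @ theta
            expected = 0.0
            for j in range(n):
                if events[j]:
                    denom = sum(np.exp(eta[r]) for r in range(n)
                                if times[r] >= times[j])
                    expected += eta[j] - np.log(denom)
            got = cox_log_partial_likelihood(theta, X, times, events)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_all_censored_warns_and_returns_unit_likelihood(self):
        with pytest.warns(UserWarning):
            L = cox_partial_likelihood([0.3], np.ones((3, 1)),
                                       [1.0, 2.0, 3.0], [False] * 3)
        assert L == 1.0


class TestElasticNetCox:
    def test_huge_penalty_zeroes_all_coefficients(self):
        X, t, e = simulate_cohort(40, 0.8, seed=1, p=3)
        fit = fit_elastic_net_cox(X, t, e, alpha=0.5, lam=50.0)
        assert np.all(fit.coefficients == 0.0)
        assert fit.selected == []

    def test_zero_penalty_matches_generic_optimizer(self):
        """Unpenalized fit agrees with direct numeric maximization of the
        Breslow log partial likelihood written out in this test."""
        rng = np.random.default_rng(2)
        for seed in range(5):
            X, t, e = simulate_cohort(10, 0.5, seed=seed, p=2)
            if e.sum() < 3:
                continue
            fit = fit_elastic_net_cox(X, t, e, alpha=0.5, lam=0)

            def negll(theta):
                eta = X @ theta
                out = 0.0
                for j in range(len(t)):
                    if e[j]:
                        denom = np.log(np.sum(np.exp(eta[t >= t[j]])))
                        out -= eta[j] - denom
                return out

            res = minimize(negll, np.zeros(2), method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12,
                                    "maxiter": 5000})
            np.testing.assert_allclose(fit.coefficients, res.x, atol=1e-4)

    def test_coefficient_norm_shrinks_with_penalty(self):
        X, t, e = simulate_cohort(60, 0.8, seed=3, p=4)
        lams = [0.02, 0.1, 0.5]
        norms = [np.linalg.norm(
            fit_elastic_net_cox(X, t, e, alpha=0.5, lam=l).coefficients)
            for l in lams]
        assert norms[0] >= norms[1] >= norms[2]

    def test_cv_lambda_is_deterministic_given_seed(self):
        X, t, e = simulate_cohort(60, 0.8, seed=4, p=5)
        a = fit_elastic_net_cox(X, t, e, alpha=0.5, lam="cv", seed=9)
        b = fit_elastic_net_cox(X, t, e, alpha=0.5, lam="cv", seed=9)
        assert a.lam == b.lam
        np.testing.assert_array_equal(a.coefficients, b.coefficients)


class TestSelectAlpha:
    def test_argmin_and_tie_rule_on_mocked_cv_curve(self, monkeypatch):
        from igvprog import survival_stats as ss

        curve = {0.2: 5.0, 0.4: 5.0, 0.3: 4.0}

        def fake_fit(covariates, times, events, alpha=0.5, lam="cv", **kw):
            return ss.PenalizedCoxFit([], np.array([]), 0.1, alpha,
                                      cv_error=curve.get(alpha, 9.0))

        monkeypatch.setattr(ss, "fit_elastic_net_cox", fake_fit)
        alpha, fit = ss.select_alpha(None, None, None)
        assert alpha == 0.3
        assert len(fit.alpha_grid_errors) == 11

        curve[0.3] = 5.0  # three-way tie at 0.2/0.3/0.4 -> smallest wins
        alpha, _ = ss.select_alpha(None, None, None)
        assert alpha == 0.2


class TestStratifiedMHTest:
    def test_single_stratum_reduces_to_ordinary_logrank(self):
        rng = np.random.default_rng(5)
        n = 60
        t = rng.exponential(1.0, n)
        e = rng.random(n) < 0.7
        g = rng.integers(0, 2, n)
        chi2, p = stratified_mh_test(g, np.zeros(n), t, e)
        ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_mirror_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 1.0, 2.0])
        e = np.array([True, False, True, False])
        g = np.array([0, 0, 1, 1])
        chi2, p = stratified_mh_test(g, np.zeros(4), t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_stratum_fixture_matches_brute_force_sum(self):
        # explicit brute-force accumulation of hypergeometric terms
        times = np.array([1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 4.5])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1], dtype=bool)
        groups = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        strata = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        U = V = 0.0
        for s in (0, 1):
            m = strata == s
            for tt in np.unique(times[m & events]):
                at = m & (times >= tt)
                n = at.sum()
                n1 = (at & (groups == 1)).sum()
                d = (m & events & (times == tt)).sum()
                d1 = (m & events & (times == tt) & (groups == 1)).sum()
                U += d1 - d * n1 / n
                if n > 1:
                    V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        chi2, _ = stratified_mh_test(groups, strata, times, events)
        assert chi2 == pytest.approx(U * U / V, rel=1e-12)

    def test_single_group_stratum_warns_and_all_uninformative_errors(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, bool)
        with pytest.warns(UserWarning):
            stratified_mh_test(np.array([0, 1, 0, 0]),
                               np.array([0, 0, 1, 1]), t, e)
        with pytest.raises(ValueError):
            stratified_mh_test(np.array([0, 0, 1, 1]),
                               np.array([0, 0, 1, 1]), t, e)


class TestCoxFits:
    def test_scale_equivariance_of_univariate_coefficient(self):
        X, t, e = simulate_cohort(80, 1.0, seed=6)
        fit1 = univariate_cox(X[:, 0], t, e)
        fit2 = univariate_cox(2 * X[:, 0], t, e)
        assert fit2.coefficients[0] == pytest.approx(fit1.coefficients[0] / 2,
                                                     rel=1e-6)

    def test_univariate_recovers_planted_coefficient(self):
        hits = 0
        for seed in range(30):
            X, t, e = simulate_cohort(500, 1.0, seed=100 + seed)
            fit = univariate_cox(X[:, 0], t, e)
            hits += 0.8 <= fit.coefficients[0] <= 1.2
        assert hits >= 27

    def test_null_univariate_p_roughly_uniform(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(300 + seed)
            t = rng.exponential(1.0, 80)
            e = rng.random(80) < 0.7
            score = rng.normal(size=80)
            ps.append(univariate_cox(score, t, e).p_values[0])
        ps = np.asarray(ps)
        # uniformity: mean near 0.5 and ~5% below 0.05
        assert abs(ps.mean() - 0.5) < 0.07
        assert (ps < 0.05).mean() < 0.12

    def test_constant_score_is_degenerate(self):
        with pytest.raises(ValueError):
            univariate_cox(np.ones(10), np.arange(1.0, 11), np.ones(10, bool))

    def test_duplicate_predictor_collinearity_named(self):
        X, t, e = simulate_cohort(50, 0.5, seed=8, p=2)
        XX = np.column_stack([X, X[:, 0]])
        with pytest.raises(ValueError, match="collinear"):
            multivariate_cox(XX, t, e, names=["a", "b", "a_copy"])

    def test_single_predictor_equals_univariate(self):
        X, t, e = simulate_cohort(60, 0.7, seed=9)
        uni = univariate_cox(X[:, 0], t, e)
        multi = multivariate_cox(X[:, :1], t, e)
        assert multi.coefficients[0] == pytest.approx(uni.coefficients[0],
                                                      rel=1e-9)

    def test_planted_two_predictor_model_within_ci(self):
        covered = 0
        for seed in range(20):
            X, t, e = simulate_cohort(500, [0.5, -0.5], seed=500 + seed, p=2)
            fit = multivariate_cox(X, t, e)
            lo, hi = fit.ci_lower, fit.ci_upper
            covered += (lo[0] <= np.exp(0.5) <= hi[0]
                        and lo[1] <= np.exp(-0.5) <= hi[1])
        assert covered >= 16

    def test_standardized_coefficients_scale_with_sd(self):
        X, t, e = simulate_cohort(120, 0.8, seed=10)
        fit = univariate_cox(X[:, 0], t, e)
        assert fit.standardized_coefficients[0] == pytest.approx(
            fit.coefficients[0] * X[:, 0].std(ddof=1))


class TestBHFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_all_ones(self):
        assert bh_fdr([0.2])[0] == 0.2
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        p = rng.random(50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_empty_input(self):
        assert len(bh_fdr([])) == 0


class TestCovariateCoding:
    def test_binarization_rules(self, small_clinical):
        binc = binarize_covariates(small_clinical.table)
        df = small_clinical.table
        assert (binc["age_ge60"] == (df["age"] >= 60)).all()
        assert (binc["stage_34"] == (df["stage"] >= 3)).all()

    def test_strata_exclude_grade(self, small_clinical):
        labels = strata_labels(small_clinical.table)
        assert len(np.unique(labels)) <= 8  # 2^3 combinations of age/stage/residual
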