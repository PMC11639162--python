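import numpy as np
import pytest
from scipy import optimize, stats

from survbal import (
    SimulationConfig,
    SurvivalOutcome,
    ValidationError,
    fit_cox,
    fit_weibull_aft,
    predict_survival_curves,
    simulate_dataset,
)
from survbal.survival import martingale_residuals


def _partial_loglik_no_ties(gamma, B, time, event):
    """Independent oracle: the written-out Breslow/Efron partial likelihood
    for distinct times, evaluated directly from its definition."""
    ll = 0.0
    for i in np.flatnonzero(event):
        risk = time >= time[i]
        ll += gamma * B[i] - np.log(np.sum(np.exp(gamma * B[risk])))
    return ll


class TestCoxOracles:
    def test_six_subject_grid_oracle(self):
        # higher-balance subjects tend to fail earlier (finite MLE)
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.ones(6, dtype=int)
        B = np.array([1.0, 0, 1, 0, 1, 0])
        out = SurvivalOutcome(time, event)
        fit = fit_cox(B, out)
        assert fit.gamma > 0
        grid = np.linspace(-3, 6, 20001)
        lls = [_partial_loglik_no_ties(g, B, time, event) for g in grid]
        g_star = grid[int(np.argmax(lls))]
        assert fit.gamma == pytest.approx(g_star, abs=2e-3)
        assert fit.loglik == pytest.approx(max(lls), abs=1e-6)

    def test_antisymmetric_pooled_gives_zero(self):
        # B and -B pooled with identical times/events: likelihood even in gamma
        time = np.concatenate([np.arange(1.0, 7)] * 2)
        event = np.ones(12, dtype=int)
        b = np.array([1.0, 0.4, -0.3, 0.9, -1.2, 0.1])
        B = np.concatenate([b, -b])
        fit = fit_cox(B, SurvivalOutcome(time, event), ties="efron")
        assert fit.gamma == pytest.approx(0.0, abs=1e-6)

    def test_lrt_matches_direct_evaluation(self):
        rng = np.random.default_rng(5)
        n = 80
        B = rng.normal(size=n)
        time = rng.exponential(np.exp(-0.8 * B))
        event = np.ones(n, dtype=int)
        out = SurvivalOutcome(time, event)
        fit = fit_cox(B, out)
        ll_hat = _partial_loglik_no_ties(fit.gamma, B, time, event)
        ll_null = _partial_loglik_no_ties(0.0, B, time, event)
        assert fit.lrt_statistic == pytest.approx(2 * (ll_hat - ll_null), abs=1e-6)
        assert fit.p_gamma == pytest.approx(stats.chi2.sf(2 * (ll_hat - ll_null), 1),
                                            abs=1e-8)


class TestCoxAgainstLifelines:
    @pytest.mark.parametrize("with_ties", [False, True])
    def test_efron_matches_lifelines(self, with_ties):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(42)
        n = 150
        B = rng.normal(size=n)
        Z = rng.normal(size=(n, 2))
        T = rng.exponential(np.exp(-(0.7 * B + 0.3 * Z[:, 0] - 0.2 * Z[:, 1])))
        C = rng.uniform(0, 3, n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
        if with_ties:
            time = np.round(time, 1) + 0.05
        out = SurvivalOutcome(time, event, Z, ("z1", "z2"))
        fit = fit_cox(B, out, ties="efron")
        df = pd.DataFrame({"T": time, "E": event, "B": B,
                           "z1": Z[:, 0], "z2": Z[:, 1]})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert fit.gamma == pytest.approx(cph.params_["B"], abs=1e-5)
        np.testing.assert_allclose(fit.beta, cph.params_[["z1", "z2"]], atol=1e-5)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)
        assert fit.se_gamma == pytest.approx(cph.standard_errors_["B"], rel=1e-4)

    def test_breslow_equals_efron_without_ties(self, rng):
        n = 60
        B = rng.normal(size=n)
        time = rng.exponential(np.exp(-0.5 * B))
        out = SurvivalOutcome(time, np.ones(n, dtype=int))
        fe = fit_cox(B, out, ties="efron")
        fb = fit_cox(B, out, ties="breslow")
        assert fe.gamma == pytest.approx(fb.gamma, abs=1e-8)


class TestCoxProperties:
    def test_rank_invariance_of_time(self, rng):
        n = 70
        B = rng.normal(size=n)
        time = rng.exponential(np.exp(-0.6 * B))
        event = (rng.uniform(size=n) < 0.8).astype(int)
        fit1 = fit_cox(B, SurvivalOutcome(time, event))
        # strictly increasing transform of time preserves ranks
        fit2 = fit_cox(B, SurvivalOutcome(np.exp(time), event))
        assert fit1.gamma == pytest.approx(fit2.gamma, abs=1e-7)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-7)

    def test_negating_balance_negates_gamma(self, rng):
        n = 70
        B = rng.normal(size=n)
        time = rng.exponential(np.exp(-0.6 * B))
        out = SurvivalOutcome(time, np.ones(n, dtype=int))
        f1 = fit_cox(B, out)
        f2 = fit_cox(-B, out)
        assert f1.gamma == pytest.approx(-f2.gamma, abs=1e-7)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_zero_events_fatal(self):
        with pytest.raises(ValidationError):
            fit_cox(np.zeros(5), SurvivalOutcome(np.arange(1.0, 6), np.zeros(5)))

    def test_monotone_likelihood_flagged_not_raised(self):
        # balance perfectly inversely ranked with time: likelihood is monotone
        time = np.arange(1.0, 11)
        B = -time
        fit = fit_cox(B, SurvivalOutcome(time, np.ones(10, dtype=int)))
        assert (not fit.converged) or fit.warnings_

    def test_loglik_dominates_null(self, strong_signal_data):
        _, data, _ = strong_signal_data
        fit = fit_cox(data.true_balance, data.outcome)
        assert fit.loglik >= fit.loglik_null
        assert 0 <= fit.p_gamma <= 1


def _weibull_mle_oracle(t):
    """Two-parameter Weibull MLE via the textbook profile root-finding:
    solve 1/k = sum(t^k log t)/sum(t^k) - mean(log t), then
    lambda = (mean(t^k))^(1/k)."""
    logt = np.log(t)
    u = t / t.max()  # the profile equation is scale invariant; avoid overflow
    logu = np.log(u)

    def profile(k):
        uk = u ** k
        return 1.0 / k - (np.sum(uk * logu) / np.sum(uk) - logu.mean())

    k = optimize.brentq(profile, 1e-3, 1e3)
    lam = np.mean(t ** k) ** (1.0 / k)
    return k, lam


class TestAFT:
    def test_null_effect_recovered(self):
        cfg = SimulationConfig(n_samples=500, n_taxa=6, gamma_true=0.0,
                               model="weibull", censoring_rate=0.1,
                               aft_intercept=2.0, seed=11)
        data = simulate_dataset(cfg)
        fit = fit_weibull_aft(data.true_balance, data.outcome)
        assert abs(fit.gamma_prime) < 3 * fit.se_gamma

    def test_constant_balance_reduces_to_weibull_mle(self, rng):
        # no censoring, constant balance: intercept/scale solve the
        # two-parameter Weibull likelihood (independent root-finding oracle)
        t = rng.weibull(1.7, size=200) * 3.0
        out = SurvivalOutcome(t, np.ones(200, dtype=int))
        fit = fit_weibull_aft(np.zeros(200), out)
        k, lam = _weibull_mle_oracle(t)
        assert fit.scale == pytest.approx(1.0 / k, rel=1e-4)
        assert fit.intercept == pytest.approx(np.log(lam), rel=1e-4)

    def test_mle_dominates_truth(self):
        cfg = SimulationConfig(n_samples=1000, n_taxa=6, gamma_true=0.5,
                               model="weibull", censoring_rate=0.1,
                               baseline_shape=2.0, aft_intercept=1.0, seed=3)
        data = simulate_dataset(cfg)
        fit = fit_weibull_aft(data.true_balance, data.outcome)
        # evaluate likelihood at the generating parameters
        from survbal.survival import _aft_negloglik
        X = np.column_stack([np.ones(1000), data.true_balance])
        theta_true = np.array([1.0, 0.5, np.log(0.5)])
        ll_true = -_aft_negloglik(theta_true, X, np.log(data.outcome.time),
                                  data.outcome.event, "weibull")
        assert fit.loglik >= ll_true - 1e-6

    def test_matches_lifelines_up_to_jacobian(self, rng):
        import pandas as pd
        from lifelines import WeibullAFTFitter

        n = 120
        B = rng.normal(size=n)
        T = np.exp(1.0 - 0.5 * B + 0.7 * np.log(rng.exponential(size=n)))
        C = rng.uniform(0, 20, n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
        fit = fit_weibull_aft(B, SurvivalOutcome(time, event))
        df = pd.DataFrame({"T": time, "E": event, "B": B})
        ll = WeibullAFTFitter().fit(df, "T", "E")
        assert fit.gamma_prime == pytest.approx(
            ll.params_[("lambda_", "B")], abs=1e-4)
        assert fit.intercept == pytest.approx(
            ll.params_[("lambda_", "Intercept")], abs=1e-4)
        assert fit.scale == pytest.approx(
            np.exp(-ll.params_[("rho_", "Intercept")]), rel=1e-4)
        # likelihoods differ by the log-time Jacobian only
        jac = np.log(time[event == 1]).sum()
        assert fit.loglik - jac == pytest.approx(ll.log_likelihood_, abs=1e-4)

    def test_negating_balance_negates_gamma(self, rng):
        n = 100
        B = rng.normal(size=n)
        T = np.exp(1.0 + 0.5 * B + 0.5 * np.log(rng.exponential(size=n)))
        out = SurvivalOutcome(T, np.ones(n, dtype=int))
        f1 = fit_weibull_aft(B, out)
        f2 = fit_weibull_aft(-B, out)
        assert f1.gamma_prime == pytest.approx(-f2.gamma_prime, abs=1e-5)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    @pytest.mark.parametrize("family", ["lognormal", "loglogistic"])
    def test_other_families_fit(self, family, rng):
        n = 150
        B = rng.normal(size=n)
        T = np.exp(1.0 + 0.4 * B + 0.5 * rng.normal(size=n))
        fit = fit_weibull_aft(B, SurvivalOutcome(T, np.ones(n, dtype=int)),
                              family=family)
        assert fit.converged
        assert fit.gamma_prime > 0


class TestPredictedCurves:
    def _cox_fit(self):
        rng = np.random.default_rng(9)
        n = 100
        B = rng.normal(size=n)
        time = rng.exponential(np.exp(-0.8 * B))
        return fit_cox(B, SurvivalOutcome(time, np.ones(n, dtype=int))), B

    def test_starts_at_one_and_nonincreasing(self):
        fit, B = self._cox_fit()
        curves = predict_survival_curves(fit, np.quantile(B, [0.25, 0.75]))
        for _, sub in curves.groupby("level"):
            s = sub.sort_values("time")["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert np.all(np.diff(s) <= 1e-12)

    def test_high_balance_curve_below_low(self):
        fit, B = self._cox_fit()
        assert fit.gamma > 0
        q1, q3 = np.quantile(B, [0.25, 0.75])
        curves = predict_survival_curves(fit, np.array([q1, q3]))
        s1 = curves[curves.level == q1].sort_values("time")["survival"].to_numpy()
        s3 = curves[curves.level == q3].sort_values("time")["survival"].to_numpy()
        assert np.all(s3 <= s1 + 1e-12)

    def test_weibull_null_effect_curves_coincide(self, rng):
        n = 200
        B = rng.normal(size=n)
        T = np.exp(1.0 + 0.5 * np.log(rng.exponential(size=n)))
        fit = fit_weibull_aft(np.zeros(n), SurvivalOutcome(T, np.ones(n, dtype=int)))
        curves = predict_survival_curves(fit, np.array([-1.0, 1.0]),
                                         times=np.linspace(0, 10, 50))
        s_lo = curves[curves.level == -1.0]["survival"].to_numpy()
        s_hi = curves[curves.level == 1.0]["survival"].to_numpy()
        np.testing.assert_allclose(s_lo, s_hi, atol=1e-12)

    def test_nonfinite_level_fatal(self):
        fit, _ = self._cox_fit()
        with pytest.raises(ValidationError):
            predict_survival_curves(fit, np.array([np.nan]))


class TestMartingaleResiduals:
    def test_matches_nelson_aalen_without_covariates(self, toy_outcome):
        from lifelines import NelsonAalenFitter

        r = martingale_residuals(toy_outcome)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(
            toy_outcome.time, toy_outcome.event)
        na = naf.cumulative_hazard_at_times(toy_outcome.time).to_numpy()
        np.testing.assert_allclose(r, toy_outcome.event - na, atol=1e-10)

    def test_events_minus_residuals_nonnegative(self, strong_signal_data):
        _, data, _ = strong_signal_data
        r = martingale_residuals(data.outcome)
        assert np.all(r <= 1.0 + 1e-12)
        assert abs(r.sum()) < 1e-8
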