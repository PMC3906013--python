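"""EOR forms, likelihood, ML fitting, profile CIs and LRTs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from thyrocal import (CohortConfig, RiskParams, excess_odds_ratio, fit_ml,
                      generate_cohort, log_likelihood, lrt, prevalence_prob,
                      profile_ci)
from thyrocal.risk import FitResult, build_model_data, _nll_grad


class TestExcessOddsRatio:
    @pytest.mark.parametrize("form", [1, 2, 3, 4, 5, 6])
    def test_zero_dose_zero_eor(self, form):
        params = RiskParams(alpha=5.0, gamma=-0.1, kappa=0.2, tau=0.1,
                            psi=0.05, eta=-1.0)
        val = excess_odds_ratio(0.0, 3.0, 17.0, 1.0, params, form)
        assert val == 0.0

    def test_linear_slope_per_gray(self):
        # linear form: EOR at 1 Gy equals the slope itself
        assert excess_odds_ratio(1.0, 8, 22, 0, RiskParams(alpha=5.78), 1) \
            == pytest.approx(5.78)

    @given(st.floats(0.0, 30.0))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_centering_identities(self, D):
        p = RiskParams(alpha=4.0, gamma=-0.08, kappa=0.3)
        lin = excess_odds_ratio(D, 8, 22, 0, RiskParams(alpha=4.0), 1)
        linexp0 = excess_odds_ratio(D, 8, 22, 0, RiskParams(alpha=4.0, gamma=0.0), 2)
        assert linexp0 == pytest.approx(lin, rel=1e-12)
        # age-at-exposure modifier vanishes at the centering age of 8
        form3_at_centre = excess_odds_ratio(D, 8.0, 22, 0, p, 3)
        form2 = excess_odds_ratio(D, 8.0, 22, 0, p, 2)
        assert form3_at_centre == pytest.approx(form2, rel=1e-12)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            excess_odds_ratio(1.0, 8, 22, 0, RiskParams(alpha=1.0), 7)


class TestPrevalenceProb:
    def test_all_zero_coefficients_gives_half(self):
        assert prevalence_prob(0.0, 8, 22, 0, RiskParams(), 1) == pytest.approx(0.5)

    def test_odds_arithmetic(self):
        # baseline odds 0.01, EOR = 1 -> p = 0.02 / 1.02
        params = RiskParams(beta0=math.log(0.01), alpha=1.0)
        p = prevalence_prob(1.0, 8, 22, 0, params, 1)
        assert p == pytest.approx(0.02 / 1.02, rel=1e-12)

    def test_increasing_in_alpha(self):
        ps = [prevalence_prob(2.0, 8, 22, 0, RiskParams(beta0=-4, alpha=a), 1)
              for a in (0.5, 1.0, 2.0, 5.0)]
        assert np.all(np.diff(ps) > 0)

    def test_model_violation_raises(self):
        from thyrocal import ModelViolationError
        with pytest.raises(ModelViolationError):
            prevalence_prob(2.0, 8, 22, 0, RiskParams(alpha=-1.0), 1)


class TestLogLikelihood:
    def test_single_subject_half(self):
        assert log_likelihood([1], [0.5]) == pytest.approx(math.log(0.5))

    def test_duplication_doubles(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.uniform(0.05, 0.95, 50)
        ll = log_likelihood(y, p)
        assert log_likelihood(np.tile(y, 2), np.tile(p, 2)) \
            == pytest.approx(2 * ll, rel=1e-12)

    def test_matches_per_record_bernoulli_sum(self, rng):
        """Internal fit objective agrees with a brute-force per-record sum."""
        cfg = CohortConfig.simple(100, gsd_a=1.2, gsd_m=1.2, alpha=3.0)
        df = generate_cohort(cfg, 21)
        d = df["D_mes"].to_numpy()
        data = build_model_data(df, d, "linexp")
        theta = np.concatenate([rng.normal(-3, 0.5, data.n_baseline), [2.0, -0.05]])
        free = np.ones(theta.size, dtype=bool)
        nll, _ = _nll_grad(theta, data, free, np.zeros(theta.size))

        brute = 0.0
        for i in range(len(df)):
            b = theta[: data.n_baseline] @ data.X[i]
            eor = 2.0 * d[i] * math.exp(-0.05 * d[i])
            odds = math.exp(b) * (1 + eor)
            p = odds / (1 + odds)
            brute += df["y"].iat[i] * math.log(p) + (1 - df["y"].iat[i]) * math.log(1 - p)
        assert -nll == pytest.approx(brute, abs=1e-12 * max(1, abs(brute)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([1, 0], [0.5])


@pytest.fixture(scope="module")
def recovery_cohort():
    # error-free doses, true linear slope 5/Gy, ~2% cases
    cfg = CohortConfig.simple(50000, dose_median=0.2, log_dose_sigma=1.4,
                              alpha=5.0, target_cases=1000)
    return generate_cohort(cfg, 42)


class TestFitML:
    def test_recovers_linear_slope(self, recovery_cohort):
        fit = fit_ml(recovery_cohort, recovery_cohort["D_mes"].to_numpy(), "linear")
        assert fit.converged
        assert fit["alpha"] == pytest.approx(5.0, rel=0.15)

    def test_scale_equivariance(self, recovery_cohort):
        d = recovery_cohort["D_mes"].to_numpy()
        f1 = fit_ml(recovery_cohort, d, "linexp")
        f2 = fit_ml(recovery_cohort, 10 * d, "linexp")
        assert f2["alpha"] == pytest.approx(f1["alpha"] / 10, rel=1e-4)
        assert f2.estimates["gamma"] == pytest.approx(f1.estimates["gamma"] / 10,
                                                      rel=1e-3, abs=1e-8)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-5)

    def test_perturbed_starts_reach_same_optimum(self, recovery_cohort):
        d = recovery_cohort["D_mes"].to_numpy()
        f1 = fit_ml(recovery_cohort, d, "linear", seed=0)
        f2 = fit_ml(recovery_cohort, d, "linear", seed=99,
                    start={"alpha": 12.0, "beta0": -2.0})
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-6)

    def test_subject_order_invariance(self, recovery_cohort):
        d = recovery_cohort["D_mes"].to_numpy()
        f1 = fit_ml(recovery_cohort, d, "linear")
        perm = np.random.default_rng(0).permutation(len(d))
        shuffled = recovery_cohort.iloc[perm].reset_index(drop=True)
        f2 = fit_ml(shuffled, d[perm], "linear")
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-6)
        assert f2["alpha"] == pytest.approx(f1["alpha"], rel=1e-5)

    def test_all_zero_doses_unidentifiable(self, recovery_cohort):
        with pytest.raises(ValueError):
            fit_ml(recovery_cohort, np.zeros(len(recovery_cohort)), "linear")

    def test_no_cases_rejected(self):
        cfg = CohortConfig.simple(200, alpha=0.0, risk_form="linear")
        df = generate_cohort(cfg, 1)
        df["y"] = 0
        with pytest.raises(ValueError):
            fit_ml(df, df["D_mes"].to_numpy(), "linear")

    def test_gamma_ci_covers_zero_under_linear_truth(self):
        """Fitting the curvature form to linear-truth data: the profile CI
        for gamma should cover 0 in >= 90% of replicates."""
        covered = 0
        reps = 50
        for s in range(reps):
            cfg = CohortConfig.simple(5000, dose_median=0.5, log_dose_sigma=1.0,
                                      alpha=5.0, target_cases=500)
            df = generate_cohort(cfg, 300 + s)
            fit = fit_ml(df, df["D_mes"].to_numpy(), "linexp")
            lo, hi = profile_ci(fit, "gamma")
            covered += (lo <= 0.0 <= hi)
        assert covered >= 0.9 * reps


class TestProfileCI:
    def test_level_zero_collapses_to_estimate(self, recovery_cohort):
        fit = fit_ml(recovery_cohort, recovery_cohort["D_mes"].to_numpy(), "linear")
        lo, hi = profile_ci(fit, "alpha", level=0.0)
        assert lo == hi == fit["alpha"]

    def test_drop_target_is_chi2_quantile(self):
        assert stats.chi2.ppf(0.95, 1) / 2 == pytest.approx(1.9207, abs=1e-4)

    def test_quadratic_likelihood_matches_wald(self):
        """On a high-information balanced logistic problem the log-likelihood
        is near-quadratic, so the profile CI must agree with the Wald CI."""
        rng = np.random.default_rng(8)
        n = 40000
        df = pd.DataFrame({
            "e": rng.uniform(0, 18, n), "a": rng.uniform(12, 32, n),
            "sex": np.where(rng.uniform(size=n) < 0.5, "male", "female"),
        })
        male = (df["sex"] == "male").astype(float).to_numpy()
        p = 1 / (1 + np.exp(-(0.2 + 0.5 * male)))
        df["y"] = (rng.uniform(size=n) < p).astype(int)
        fit = fit_ml(df, np.zeros(n), "null", n_age_categories=2)
        lo, hi = profile_ci(fit, "beta_sex")
        # Wald from a finite-difference Hessian of the same likelihood
        names = list(fit.data.param_names)
        free = np.ones(len(names), dtype=bool)
        eps = 1e-5
        k = names.index("beta_sex")
        H = np.zeros((len(names), len(names)))
        for j in range(len(names)):
            tp, tm = fit.theta.copy(), fit.theta.copy()
            tp[j] += eps
            tm[j] -= eps
            _, gp = _nll_grad(tp, fit.data, free, np.zeros(len(names)))
            _, gm = _nll_grad(tm, fit.data, free, np.zeros(len(names)))
            H[:, j] = (gp - gm) / (2 * eps)
        se = math.sqrt(np.linalg.inv(H)[k, k])
        z = stats.norm.ppf(0.975)
        est = fit["beta_sex"]
        assert lo == pytest.approx(est - z * se, rel=2e-3)
        assert hi == pytest.approx(est + z * se, rel=2e-3)


class TestLRT:
    def _dummy(self, names, ll):
        return FitResult(form="linear", param_names=tuple(names), estimates={},
                         loglik=ll, converged=True, grad_norm=0.0, n=100,
                         cases=10, age_edges=())

    def test_identical_fits_give_p_one(self):
        a = self._dummy(("beta0", "alpha"), -50.0)
        b = self._dummy(("beta0", "alpha", "gamma"), -50.0)
        stat, df, p = lrt(a, b)
        assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_chi2_quantile_identity(self):
        a = self._dummy(("beta0",), -50.0)
        b = self._dummy(("beta0", "alpha"), -50.0 + 3.8415 / 2)
        stat, df, p = lrt(a, b)
        assert stat == pytest.approx(3.8415)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_non_nested_rejected(self):
        a = self._dummy(("beta0", "kappa"), -50.0)
        b = self._dummy(("beta0", "alpha"), -49.0)
        with pytest.raises(ValueError):
            lrt(a, b)
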