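"""Mixed-logit likelihood, fitting, Wald inference and parametric bootstrap."""

import json
import subprocess

import numpy as np
import pytest
from scipy.special import expit

import boubakit as bk
from boubakit import reference as ref
from boubakit.glmm import (
    DataError,
    MixedLogit,
    parametric_bootstrap_se,
    wald_ci,
    wald_test,
)
from boubakit.pipeline import write_trials


def brute_force_loglik(X, y, subj, beta, sigma, half_width=8.0, n_grid=20_001):
    """Trapezoid integration of each subject's marginal likelihood."""
    grid = np.linspace(-half_width * sigma, half_width * sigma, n_grid)
    total = 0.0
    for i in np.unique(subj):
        m = subj == i
        eta = X[m] @ beta
        ll_b = (
            y[m][:, None] * (eta[:, None] + grid)
            - np.logaddexp(0, eta[:, None] + grid)
        ).sum(0)
        dens = np.exp(ll_b) * np.exp(-(grid**2) / (2 * sigma**2)) / (
            sigma * np.sqrt(2 * np.pi)
        )
        total += np.log(np.trapezoid(dens, grid))
    return total


class TestWald:
    def test_ci_is_plus_minus_196_se(self):
        assert wald_ci(0, 1) == pytest.approx((-1.96, 1.96))

    def test_ci_matches_published_us_rows(self):
        lo, hi = wald_ci(0.394, 0.014)
        assert (round(hi, 3), round(lo, 3)) == (0.421, 0.367)
        lo, hi = wald_ci(0.089, 0.002)
        assert (round(lo, 3), round(hi, 3)) == (0.085, 0.093)

    def test_z_and_p(self):
        z, p = wald_test(0, 1)
        assert z == 0 and p == pytest.approx(1.0)
        _, p = wald_test(1.96, 1)
        assert p == pytest.approx(0.05, abs=1e-3)
        z, p = wald_test(0.394, 0.014)
        assert z == pytest.approx(28.14, abs=0.01)
        assert p < 1e-10

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(1.0, 0.0)
        with pytest.raises(ValueError):
            wald_test(1.0, -1.0)


class TestMarginalLikelihood:
    def test_agq_matches_brute_force_integration(self, tiny_mixed_data):
        X, y, subj, beta, sigma = tiny_mixed_data
        ml = MixedLogit(X, y, subj, nodes=15)
        ll = ml.loglik(beta, sigma)
        oracle = brute_force_loglik(X, y, subj, beta, sigma)
        assert abs(ll - oracle) < 1e-4

    def test_agq_accuracy_away_from_generating_values(self, tiny_mixed_data):
        X, y, subj, _, _ = tiny_mixed_data
        ml = MixedLogit(X, y, subj, nodes=15)
        for beta, sigma in [(np.array([0.3, -1.0]), 0.5), (np.array([-2.0, 0.1]), 2.0)]:
            assert abs(ml.loglik(beta, sigma) - brute_force_loglik(X, y, subj, beta, sigma)) < 1e-4

    def test_sigma_zero_is_plain_bernoulli_loglik(self, tiny_mixed_data):
        X, y, subj, beta, _ = tiny_mixed_data
        ml = MixedLogit(X, y, subj)
        eta = X @ beta
        plain = float(np.sum(y * eta - np.logaddexp(0, eta)))
        assert ml.loglik(beta, 0.0) == pytest.approx(plain)

    def test_two_factor_laplace_near_brute_force(self):
        """Joint Laplace on a tiny two-group instance tracks 2-D quadrature."""
        rng = np.random.default_rng(8)
        S, T = 4, 8
        subj = np.repeat(np.arange(S), T)
        grp = np.repeat(np.array([0, 0, 1, 1]), T)
        X = np.column_stack([np.ones(S * T), rng.normal(size=S * T)])
        beta, sigma, sg = np.array([-0.5, 0.8]), 1.2, 0.6
        b, c = rng.normal(0, sigma, S), rng.normal(0, sg, 2)
        y = (rng.random(S * T) < expit(X @ beta + b[subj] + c[grp])).astype(float)
        ml = MixedLogit(X, y, subj, group=grp)
        ll = ml.loglik(beta, sigma, sg)
        # Nested trapezoid: integrate subjects given c, then c per group.
        bgrid = np.linspace(-8 * sigma, 8 * sigma, 4001)
        cgrid = np.linspace(-6 * sg, 6 * sg, 401)
        total = 0.0
        for g in range(2):
            Lg = np.ones_like(cgrid)
            for i in np.unique(subj[grp == g]):
                m = subj == i
                eta = X[m] @ beta
                Li = np.empty_like(cgrid)
                for j, cv in enumerate(cgrid):
                    ll_b = (
                        y[m][:, None] * (eta[:, None] + cv + bgrid)
                        - np.logaddexp(0, eta[:, None] + cv + bgrid)
                    ).sum(0)
                    dens = np.exp(ll_b - bgrid**2 / (2 * sigma**2))
                    Li[j] = np.trapezoid(dens, bgrid) / (sigma * np.sqrt(2 * np.pi))
                Lg *= Li
            dens_c = Lg * np.exp(-(cgrid**2) / (2 * sg**2)) / (sg * np.sqrt(2 * np.pi))
            total += np.log(np.trapezoid(dens_c, cgrid))
        assert ll == pytest.approx(total, abs=0.2)

    def test_group_variance_boundary_continuity(self):
        rng = np.random.default_rng(9)
        subj = np.repeat(np.arange(4), 8)
        grp = np.repeat(np.array([0, 0, 1, 1]), 8)
        X = np.ones((32, 1))
        y = (rng.random(32) < 0.4).astype(float)
        ml2 = MixedLogit(X, y, subj, group=grp)
        ml1 = MixedLogit(X, y, subj, nodes=1)
        beta = np.array([-0.3])
        assert ml2.loglik(beta, 1.0, 1e-9) == pytest.approx(ml1.loglik(beta, 1.0), abs=1e-6)


class TestFitting:
    def test_sigma_fixed_at_zero_matches_plain_logistic(self, us_trials_small):
        """Degenerate random effect: coefficients equal a GLM fit to 1e-6."""
        import statsmodels.api as sm

        from boubakit.model_selection import build_design_matrix

        fit = bk.fit_logistic_mixed(us_trials_small, "base", fix_sigma_id=0.0)
        dm = build_design_matrix(us_trials_small, 1)
        glm = sm.GLM(dm.y, dm.X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            [fit.coefficients[k] for k in dm.names], glm.params, atol=1e-6
        )
        assert fit.n_parameters == 4

    def test_laplace_fit_matches_lme4_glmer(self, us_trials_small, tmp_path):
        """Same data, same (Laplace) integral: coefficients, sigma and logLik
        agree with R's glmer, the standard fitter for this model class."""
        csv = tmp_path / "trials.csv"
        write_trials(us_trials_small, csv)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages({library(lme4); library(jsonlite)})\n"
            f"d <- read.csv('{csv}')\n"
            "d$amp <- d$amplitude * 100\n"
            "m <- glmer(response ~ 1 + frequency + amp + spikiness + (1|participant_id),\n"
            "           data=d, family=binomial, nAGQ=1)\n"
            "cat(toJSON(list(coef=as.numeric(fixef(m)),\n"
            "                sigma=as.numeric(sqrt(unlist(VarCorr(m)))),\n"
            "                ll=as.numeric(logLik(m))), digits=10))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        r = json.loads(out.stdout)
        fit = bk.fit_logistic_mixed(us_trials_small, "base", nodes=1)
        mine = [fit.coefficients[k] for k in ("intercept", "frequency", "amplitude", "spikiness")]
        np.testing.assert_allclose(mine, r["coef"], atol=5e-3)
        assert fit.variance_components["sigma_id"] == pytest.approx(r["sigma"][0], abs=5e-3)
        assert fit.log_likelihood == pytest.approx(r["ll"][0], abs=0.01)

    def test_recovers_generating_values_small_scale(self, us_fit_small):
        """30-subject single-replicate fit lands near the generating truth."""
        c = us_fit_small.coefficients
        assert c["frequency"] == pytest.approx(0.394, abs=0.1)
        assert c["amplitude"] == pytest.approx(0.089, abs=0.03)
        assert us_fit_small.converged
        assert us_fit_small.deviance == pytest.approx(-2 * us_fit_small.log_likelihood)

    def test_ci_brackets_coefficient(self, us_fit_small):
        for k, v in us_fit_small.coefficients.items():
            assert us_fit_small.ci_lower[k] < v < us_fit_small.ci_upper[k]

    def test_wald_coverage_small_replicates(self):
        """95% CIs for the frequency slope cover the truth in >= 90/100
        reduced-size replicates."""
        hits = 0
        for rep in range(100):
            trials = bk.simulate_group(ref.US_MODEL, 20, seed=1000 + rep)
            fit = bk.fit_logistic_mixed(trials, "base", nodes=5)
            if fit.ci_lower["frequency"] <= 0.394 <= fit.ci_upper["frequency"]:
                hits += 1
        assert hits >= 90

    def test_all_identical_responses_diagnosed(self, us_trials_small):
        bad = us_trials_small.copy()
        bad["response"] = 1
        with pytest.raises(DataError):
            bk.fit_logistic_mixed(bad, "base")


class TestBootstrap:
    def test_deterministic_for_fixed_seed(self):
        trials = bk.simulate_group(ref.US_MODEL, 15, seed=42)
        fit1 = bk.fit_logistic_mixed(trials, "base", nodes=5)
        se1 = parametric_bootstrap_se(fit1, n_boot=50, seed=9)
        fit2 = bk.fit_logistic_mixed(trials, "base", nodes=5)
        se2 = parametric_bootstrap_se(fit2, n_boot=50, seed=9)
        assert se1 == se2

    def test_bootstrap_se_tracks_hessian_se(self):
        """Asymptotic agreement: bootstrap and Hessian SEs within 1.5x."""
        trials = bk.simulate_group(ref.US_MODEL, 30, seed=77)
        fit = bk.fit_logistic_mixed(trials, "base", nodes=5)
        se_b = parametric_bootstrap_se(fit, n_boot=60, seed=3)
        for k in ("frequency", "amplitude", "spikiness"):
            ratio = se_b[k] / fit.se_hessian[k]
            assert 1 / 1.5 < ratio < 1.5, (k, ratio)

    def test_intercept_only_bootstrap_matches_binomial_se(self):
        """With no slopes and no random effect the bootstrap SE of the
        intercept approaches the delta-method binomial SE on the logit scale."""
        rng = np.random.default_rng(5)
        n, S = 3600, 50
        X = np.ones((n, 1))
        subj = np.repeat(np.arange(S), n // S)
        y = (rng.random(n) < expit(0.4)).astype(float)
        ml = MixedLogit(X, y, subj, names=["intercept"])
        fit = ml.fit(fix_sigma_id=0.0)
        se_b = parametric_bootstrap_se(fit, n_boot=100, seed=8)
        p = float(expit(fit.coefficients["intercept"]))
        closed_form = 1.0 / np.sqrt(n * p * (1 - p))
        assert se_b["intercept"] == pytest.approx(closed_form, rel=0.2)

    def test_too_few_replicates_rejected(self, us_fit_small):
        with pytest.raises(ValueError):
            parametric_bootstrap_se(us_fit_small, n_boot=10)
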