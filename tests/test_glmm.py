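"""GLMM engine: oracle agreement, parameter recovery, selection, inference."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import make_binomial_mixed
from effortbench.glmm import (ModelSpec, add_interactions_lrt,
                              backward_select_aic, fit_glmm, r2_nakagawa,
                              overdispersion_check, standardized_coefficients)
from oracles import agq_binomial_loglik


def expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestSpecParsing:
    def test_formula_roundtrip(self):
        spec = ModelSpec.from_formula(
            "y ~ a + b + a:b + (1 + a | g) + (1 | item)", "binomial")
        assert spec.response == "y"
        assert spec.fixed == ("a", "b", "a:b")
        assert spec.random[0].group == "g"
        assert spec.random[0].slopes == ("a",)
        assert spec.random[1].slopes == ()
        assert "(1 + a | g)" in spec.formula

    def test_slope_without_fixed_term_rejected(self):
        with pytest.raises(ValueError, match="matching fixed term"):
            ModelSpec.from_formula("y ~ b + (1 + a | g)", "binomial")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ModelSpec("y", "poisson", ("x",))


class TestOracles:
    def test_matches_glm_when_no_group_effect(self):
        """Simulated with zero random-effect variance, the mixed fit
        collapses onto the ordinary GLM solution."""
        df = make_binomial_mixed(20, 30, (-0.3, 0.8), sd=0.0, seed=1)
        fit = fit_glmm(ModelSpec.from_formula("y ~ x + (1 | g)", "binomial"), df)
        glm = sm.GLM(df.y, sm.add_constant(df.x),
                     family=sm.families.Binomial()).fit()
        assert fit.singular  # variance estimated at (numerically) zero
        assert fit.params.to_numpy() == pytest.approx(
            np.asarray(glm.params), abs=1e-3)
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-3)

    def test_gamma_matches_glm_when_no_group_effect(self):
        rng = np.random.default_rng(2)
        n = 500
        x = rng.normal(size=n)
        mu = np.exp(0.4 + 0.3 * x)
        y = rng.gamma(5.0, mu / 5.0)
        df = pd.DataFrame({"y": y, "x": x, "g": np.arange(n) % 10})
        fit = fit_glmm(ModelSpec.from_formula("y ~ x + (1 | g)", "gamma"), df)
        glm = sm.GLM(y, sm.add_constant(x),
                     family=sm.families.Gamma(sm.families.links.Log())).fit()
        assert fit.params.to_numpy() == pytest.approx(
            np.asarray(glm.params), abs=5e-3)
        assert fit.shape == pytest.approx(5.0, rel=0.25)

    def test_laplace_close_to_adaptive_quadrature(self):
        """Laplace log-likelihood within 0.05 of 50-node adaptive GH on a
        moderate-variance single-intercept model, with the gap shrinking as
        clusters grow."""
        df_small = make_binomial_mixed(12, 10, (0.3, 0.5), sd=0.5, seed=0)
        spec = ModelSpec.from_formula("y ~ x + (1 | g)", "binomial")
        fit = fit_glmm(spec, df_small)
        sigma = max(np.sqrt(fit.variance_components["g:(Intercept)"]), 1e-6)
        gap_small = fit.loglik - agq_binomial_loglik(
            fit.params.to_numpy(), sigma, df_small)
        assert abs(gap_small) < 0.05

        df_mid = make_binomial_mixed(12, 10, (0.3, 0.5), sd=1.0, seed=1)
        df_big = make_binomial_mixed(12, 60, (0.3, 0.5), sd=1.0, seed=1)
        gaps = []
        for df in (df_mid, df_big):
            f = fit_glmm(spec, df)
            s = max(np.sqrt(f.variance_components["g:(Intercept)"]), 1e-6)
            gaps.append(abs(f.loglik
                            - agq_binomial_loglik(f.params.to_numpy(), s, df)))
        assert gaps[1] < gaps[0]

    def test_agrees_with_lme4(self):
        df = make_binomial_mixed(25, 30, (0.2, 0.6), sd=0.8, seed=5)
        fit = fit_glmm(ModelSpec.from_formula("y ~ x + (1 | g)", "binomial"), df)
        with tempfile.TemporaryDirectory() as tmp:
            csv = Path(tmp) / "d.csv"
            df.to_csv(csv, index=False)
            script = (
                f"suppressMessages(library(lme4));"
                f"d <- read.csv('{csv}');"
                f"m <- glmer(y ~ x + (1 | g), data=d, family=binomial);"
                f"cat(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)))"
            )
            out = subprocess.run(["Rscript", "-e", script], timeout=300,
                                 capture_output=True, text=True, check=True)
        b0, b1, sd, ll = map(float, out.stdout.split())
        assert fit.params.iloc[0] == pytest.approx(b0, abs=0.05)
        assert fit.params.iloc[1] == pytest.approx(b1, abs=0.05)
        assert np.sqrt(fit.variance_components["g:(Intercept)"]) == \
            pytest.approx(sd, abs=0.05)
        assert fit.loglik == pytest.approx(ll, abs=0.5)


class TestRecoveryAndCoverage:
    def test_ci_coverage_in_simulate_and_refit(self):
        """95% Wald CIs for the slope cover the generating value in >= 90%
        of simulate-and-refit replicates."""
        spec = ModelSpec.from_formula("y ~ x + (1 | g)", "binomial")
        beta1 = 0.5
        covered = 0
        reps = 150
        for r in range(reps):
            df = make_binomial_mixed(30, 15, (0.0, beta1), sd=0.7,
                                     seed=1000 + r)
            fit = fit_glmm(spec, df)
            row = fit.coefficients.iloc[1]
            covered += int(row.ci_low <= beta1 <= row.ci_high)
        assert covered / reps >= 0.90

    def test_gamma_mixed_parameter_recovery(self):
        rng = np.random.default_rng(3)
        n_groups, per = 60, 40
        g = np.repeat(np.arange(n_groups), per)
        x = rng.normal(size=n_groups * per)
        b = rng.normal(0, 0.3, n_groups)
        mu = np.exp(0.5 + 0.4 * x + b[g])
        y = rng.gamma(6.0, mu / 6.0)
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        fit = fit_glmm(ModelSpec.from_formula("y ~ x + (1 | g)", "gamma"), df)
        assert fit.converged
        assert fit.params.iloc[1] == pytest.approx(0.4, abs=0.05)
        assert np.sqrt(fit.variance_components["g:(Intercept)"]) == \
            pytest.approx(0.3, abs=0.1)
        assert fit.shape == pytest.approx(6.0, rel=0.2)

    def test_random_slope_variance_recovered(self):
        rng = np.random.default_rng(7)
        n_groups, per = 80, 40
        g = np.repeat(np.arange(n_groups), per)
        x = rng.normal(size=n_groups * per)
        b0 = rng.normal(0, 0.8, n_groups)
        b1 = rng.normal(0, 0.5, n_groups)
        y = (rng.random(len(g)) < expit(0.2 + 0.5 * x + b0[g] + b1[g] * x)
             ).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        fit = fit_glmm(ModelSpec.from_formula("y ~ x + (1 + x | g)",
                                              "binomial"), df)
        assert np.sqrt(fit.variance_components["g:(Intercept)"]) == \
            pytest.approx(0.8, abs=0.25)
        assert np.sqrt(fit.variance_components["g:x"]) == \
            pytest.approx(0.5, abs=0.25)


class TestSelection:
    def test_noise_removed_strong_retained(self):
        """Backward AIC elimination drops a pure-noise covariate in the
        majority of replicates and retains a strong one in nearly all."""
        kept_strong = removed_noise = 0
        reps = 12
        for r in range(reps):
            rng = np.random.default_rng(200 + r)
            g = np.repeat(np.arange(25), 25)
            x1 = rng.normal(size=len(g))
            x2 = rng.normal(size=len(g))
            b = rng.normal(0, 0.5, 25)
            y = (rng.random(len(g)) < expit(0.8 * x1 + b[g])).astype(float)
            df = pd.DataFrame({"y": y, "x1": x1, "x2": x2, "g": g})
            spec = ModelSpec.from_formula("y ~ x1 + x2 + (1 | g)", "binomial")
            best, trace = backward_select_aic(spec, df)
            kept_strong += int("x1" in best.spec.fixed)
            removed_noise += int("x2" not in best.spec.fixed)
            full_aic = trace[0]["aic"]
            assert best.aic <= full_aic + 1e-9
        assert kept_strong == reps
        assert removed_noise > reps / 2

    def test_random_slope_dropped_when_superfluous(self):
        df = make_binomial_mixed(30, 30, (0.2, 0.6), sd=0.6, seed=9)
        spec = ModelSpec.from_formula("y ~ x + (1 + x | g)", "binomial")
        best, trace = backward_select_aic(spec, df)
        # the data carry no slope variance: selection should simplify
        assert all(rt.slopes == () for rt in best.spec.random)
        actions = [t["action"] for t in trace]
        assert any(a.startswith("remove:slope:x|g") for a in actions)


class TestInteractionsLRT:
    def test_zero_new_terms_is_null_test(self):
        df = make_binomial_mixed(10, 20, (0.0, 0.5), sd=0.4, seed=11)
        fit = fit_glmm(ModelSpec.from_formula("y ~ x + (1 | g)", "binomial"), df)
        aug, res = add_interactions_lrt(fit, [], df)
        assert res == {"chi2": 0.0, "df": 0, "p_value": 1.0, "kept": False}

    def test_chi2_is_twice_loglik_difference(self):
        rng = np.random.default_rng(12)
        g = np.repeat(np.arange(20), 30)
        x1 = rng.normal(size=len(g))
        x2 = (np.arange(len(g)) % 2).astype(float)
        b = rng.normal(0, 0.4, 20)
        y = (rng.random(len(g)) < expit(0.4 * x1 + 0.3 * x2
                                        + 0.8 * x1 * x2 + b[g])).astype(float)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2, "g": g})
        base = fit_glmm(ModelSpec.from_formula("y ~ x1 + x2 + (1 | g)",
                                               "binomial"), df)
        aug, res = add_interactions_lrt(base, ["x1:x2"], df)
        assert res["chi2"] == pytest.approx(
            2 * (aug.loglik - base.loglik), abs=1e-9)
        assert res["df"] == 1

    def test_true_interaction_detected_with_power(self):
        """A strong simulated interaction is detected (p < 0.05) in >= 80%
        of replicates."""
        detected = 0
        reps = 15
        for r in range(reps):
            rng = np.random.default_rng(400 + r)
            g = np.repeat(np.arange(20), 40)
            x1 = rng.normal(size=len(g))
            x2 = np.tile([0.0, 1.0], len(g) // 2)
            b = rng.normal(0, 0.4, 20)
            y = (rng.random(len(g)) < expit(0.3 * x1 + 0.2 * x2
                                            + 0.8 * x1 * x2 + b[g])
                 ).astype(float)
            df = pd.DataFrame({"y": y, "x1": x1, "x2": x2, "g": g})
            base = fit_glmm(ModelSpec.from_formula(
                "y ~ x1 + x2 + (1 | g)", "binomial"), df)
            _, res = add_interactions_lrt(base, ["x1:x2"], df)
            detected += int(res["kept"])
        assert detected / reps >= 0.80


class TestStandardization:
    def test_scale_invariance_of_continuous_covariate(self):
        df = make_binomial_mixed(20, 25, (0.1, 0.6), sd=0.4, seed=14)
        spec = ModelSpec.from_formula("y ~ x + (1 | g)", "binomial")
        fit = fit_glmm(spec, df)
        std = standardized_coefficients(fit, df)
        df10 = df.assign(x=df.x * 10)
        std10 = standardized_coefficients(fit_glmm(spec, df10), df10)
        assert std.params["x"] == pytest.approx(std10.params["x"], rel=1e-4)
        # and the standardized slope is raw slope times SD(x)
        assert std.params["x"] == pytest.approx(
            fit.params["x"] * df.x.std(ddof=0), rel=1e-4)

    def test_binary_dummy_left_unscaled(self):
        rng = np.random.default_rng(15)
        g = np.repeat(np.arange(15), 20)
        d = (np.arange(len(g)) % 2).astype(float)
        b = rng.normal(0, 0.4, 15)
        y = (rng.random(len(g)) < expit(0.2 + 0.7 * d + b[g])).astype(float)
        df = pd.DataFrame({"y": y, "d": d, "g": g})
        fit = fit_glmm(ModelSpec.from_formula("y ~ d + (1 | g)", "binomial"), df)
        std = standardized_coefficients(fit, df)
        assert std.params["d"] == pytest.approx(fit.params["d"], rel=1e-6)

    def test_participant_level_covariate_standardized_once(self):
        """A covariate constant within participants (like a word score in
        quiet) is z-scored across rows, matching the refit convention."""
        rng = np.random.default_rng(16)
        g = np.repeat(np.arange(20), 20)
        w = rng.uniform(0.7, 1.0, 20)[g]
        b = rng.normal(0, 0.3, 20)
        y = (rng.random(len(g)) < expit(0.2 + 1.5 * (w - 0.85) + b[g])
             ).astype(float)
        df = pd.DataFrame({"y": y, "w": w, "g": g})
        fit = fit_glmm(ModelSpec.from_formula("y ~ w + (1 | g)", "binomial"), df)
        std = standardized_coefficients(fit, df)
        assert std.params["w"] == pytest.approx(
            fit.params["w"] * df.w.std(ddof=0), rel=1e-3)


class TestR2AndDispersion:
    def test_intercept_only_marginal_zero(self):
        df = make_binomial_mixed(10, 30, (0.4, 0.0), sd=0.5, seed=17)
        fit = fit_glmm(ModelSpec("y", "binomial", (), ()), df)
        marg, cond = r2_nakagawa(fit)
        assert marg == pytest.approx(0.0, abs=1e-10)
        assert cond >= marg

    def test_conditional_at_least_marginal(self):
        df = make_binomial_mixed(25, 25, (0.2, 0.7), sd=0.8, seed=18)
        fit = fit_glmm(ModelSpec.from_formula("y ~ x + (1 | g)", "binomial"), df)
        assert fit.conditional_r2 >= fit.marginal_r2 >= 0.0

    def test_r2_matches_hand_plugin_identity(self):
        """The reported R2 equals the link-scale variance decomposition
        computed by hand from the fitted parameters."""
        df = make_binomial_mixed(40, 25, (0.1, 0.8), sd=0.7, seed=19)
        fit = fit_glmm(ModelSpec.from_formula("y ~ x + (1 | g)", "binomial"), df)
        bhat = fit.params
        var_f = np.var(bhat["Intercept"] + bhat["x"] * df.x.to_numpy())
        s2 = fit.variance_components["g:(Intercept)"]
        resid = np.pi ** 2 / 3
        assert fit.marginal_r2 == pytest.approx(
            var_f / (var_f + s2 + resid), rel=1e-10)
        assert fit.conditional_r2 == pytest.approx(
            (var_f + s2) / (var_f + s2 + resid), rel=1e-10)

    def test_r2_close_to_plugin_truth_at_scale(self):
        """With generous cluster sizes (where the Laplace bias is small) the
        computed R2 lands near the analytic plug-in from the generating
        parameters."""
        rng = np.random.default_rng(19)
        n_groups, per, beta1, sd = 150, 60, 1.0, 0.6
        g = np.repeat(np.arange(n_groups), per)
        x = rng.normal(size=len(g))
        b = rng.normal(0, sd, n_groups)
        y = (rng.random(len(g)) < expit(beta1 * x + b[g])).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        fit = fit_glmm(ModelSpec.from_formula("y ~ x + (1 | g)", "binomial"), df)
        resid = np.pi ** 2 / 3
        var_f = beta1 ** 2 * np.var(x)
        truth_marg = var_f / (var_f + sd ** 2 + resid)
        truth_cond = (var_f + sd ** 2) / (var_f + sd ** 2 + resid)
        assert fit.marginal_r2 == pytest.approx(truth_marg, abs=0.02)
        assert fit.conditional_r2 == pytest.approx(truth_cond, abs=0.04)

    def test_dispersion_near_one_under_correct_model(self):
        rng = np.random.default_rng(20)
        n_groups = 40
        m = 20
        g = np.arange(n_groups)
        p = expit(rng.normal(0.3, 0.5, n_groups))
        successes = rng.binomial(m, p)
        df = pd.DataFrame({"y": successes / m, "m": m, "g": g,
                           "x": rng.normal(size=n_groups)})
        spec = ModelSpec("y", "binomial", ("x",),
                         random=(), trials="m")
        # grouped binomial with no random effect and true logit noise would
        # be overdispersed; instead simulate exactly from the fitted family
        p0 = expit(0.3)
        df["y"] = rng.binomial(m, p0, n_groups) / m
        fit = fit_glmm(spec, df)
        ratio, flag = overdispersion_check(fit)
        assert ratio == pytest.approx(1.0, abs=0.35)
        assert not flag

    def test_betabinomial_contamination_flagged(self):
        rng = np.random.default_rng(21)
        n, m = 150, 30
        p = rng.beta(2, 2, n)  # strong extra-binomial variation
        df = pd.DataFrame({"y": rng.binomial(m, p, n) / m, "m": m,
                           "x": rng.normal(size=n)})
        fit = fit_glmm(ModelSpec("y", "binomial", ("x",), (), trials="m"), df)
        ratio, flag = overdispersion_check(fit)
        assert ratio > 1.5
        assert flag

    def test_ratio_matches_manual_pearson_sum(self):
        df = make_binomial_mixed(15, 20, (0.2, 0.5), sd=0.4, seed=22)
        fit = fit_glmm(ModelSpec.from_formula("y ~ x + (1 | g)", "binomial"), df)
        eta = fit._eta
        mu = expit(eta)
        pearson = np.sum((fit._design.y - mu) ** 2 / (mu * (1 - mu)))
        assert fit.dispersion_ratio == pytest.approx(
            pearson / (fit.n_obs - fit.n_params), rel=1e-10)


class TestInputValidation:
    def test_gamma_requires_positive_response(self):
        df = pd.DataFrame({"y": [1.0, -0.5, 2.0], "g": [0, 0, 1]})
        with pytest.raises(ValueError, match="positive"):
            fit_glmm(ModelSpec.from_formula("y ~ (1 | g)", "gamma"), df)

    def test_binomial_requires_unit_interval(self):
        df = pd.DataFrame({"y": [0.0, 2.0], "g": [0, 1]})
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fit_glmm(ModelSpec.from_formula("y ~ (1 | g)", "binomial"), df)

    def test_missing_responses_dropped(self):
        df = make_binomial_mixed(10, 20, (0.1, 0.5), sd=0.3, seed=23)
        df.loc[:9, "y"] = np.nan
        fit = fit_glmm(ModelSpec.from_formula("y ~ x + (1 | g)", "binomial"), df)
        assert fit.n_obs == len(df) - 10
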