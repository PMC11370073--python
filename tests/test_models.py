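"""Spline basis, mixed-model fitting, marginal means and inference."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from actitraj import models, synth

SPEC = models.SplineSpec(knots=synth.GENERATOR_KNOTS)


def rcs_oracle(x, knots):
    """Independent truncated-power evaluation, written as explicit loops."""
    t = list(knots)
    k = len(t)
    out = []
    for xi in x:
        row = [xi]
        for j in range(k - 2):
            def p3(v):
                return max(v, 0.0) ** 3
            term = (
                p3(xi - t[j])
                - p3(xi - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + p3(xi - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
            ) / (t[k - 1] - t[0]) ** 2
            row.append(term)
        out.append(row)
    return np.array(out)


class TestRcsBasis:
    def test_left_tail_exactly_linear(self):
        x = np.linspace(0.0, SPEC.knots[0], 20)
        basis = models.rcs_basis(x, SPEC)
        np.testing.assert_array_equal(basis[:, 1:], 0.0)

    def test_right_tail_linear_by_second_difference(self):
        x = np.linspace(SPEC.knots[-1], SPEC.knots[-1] + 3, 200)
        basis = models.rcs_basis(x, SPEC)
        second_diff = np.diff(basis, n=2, axis=0)
        assert np.abs(second_diff).max() < 1e-9

    def test_matches_formula_oracle_on_random_points(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1.0, 8.0, 100)
        np.testing.assert_allclose(
            models.rcs_basis(x, SPEC), rcs_oracle(x, SPEC.knots), atol=1e-10
        )

    def test_continuity_of_value_and_derivatives_at_knots(self):
        for t in SPEC.knots:
            eps = 1e-6
            x = np.array([t - 2 * eps, t - eps, t, t + eps, t + 2 * eps])
            b = models.rcs_basis(x, SPEC)
            d2 = np.diff(b, n=2, axis=0) / eps**2  # curvature jump check
            assert np.abs(np.diff(d2, axis=0)).max() < 1e-2

    def test_nonincreasing_knots_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            models.SplineSpec(knots=(2.0, 2.0, 4.0, 5.0))


class TestPlaceKnots:
    def test_uniform_ages_give_expected_quantiles(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(2, 7, 20_000)
        spec = models.place_knots(ages)
        np.testing.assert_allclose(spec.knots, (2.25, 3.75, 5.25, 6.75), atol=0.05)

    def test_identical_ages_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            models.place_knots(np.full(50, 4.0))

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(2, 7, 500)
        assert models.place_knots(ages).knots == models.place_knots(ages.copy()).knots


class TestFitLmm:
    def test_noise_free_cohort_recovered_exactly(self):
        p = synth.CohortSimParams(
            n_children=100, residual_sd=0.0, random_intercept_sd=0.0, seed=1
        )
        cohort, truth = synth.simulate_cohort(p)
        fit = models.fit_lmm(cohort, "total_pa", SPEC, covariates=())
        mm = models.marginal_means(fit, ages=SPEC.knots)
        for age in SPEC.knots:
            for sex in ("male", "female"):
                expected = float(truth.mean_outcome("total_pa", age, sex))
                assert mm.at(age, sex).estimate == pytest.approx(expected, rel=1e-6)

    def test_variance_components_within_15_percent(self):
        p = synth.CohortSimParams(
            n_children=500, random_intercept_sd=20.0, residual_sd=30.0, seed=0
        )
        cohort, _ = synth.simulate_cohort(p)
        fit = models.fit_lmm(cohort, "total_pa", SPEC, covariates=())
        assert fit.random_intercept_var == pytest.approx(400.0, rel=0.15)
        assert fit.residual_var == pytest.approx(900.0, rel=0.15)

    def test_sex_effect_ci_coverage(self):
        """The +10 min male offset is inside its 95% CI at ~nominal rate."""
        hits = 0
        n_rep = 50
        for r in range(n_rep):
            cohort, _ = synth.simulate_cohort(
                synth.CohortSimParams(n_children=150, seed=9_000 + r)
            )
            fit = models.fit_lmm(cohort, "total_pa", SPEC, covariates=())
            mm = models.marginal_means(fit, ages=(4.0,))
            male, female = mm.at(4.0, "male"), mm.at(4.0, "female")
            diff = male.estimate - female.estimate
            # CI of the sex contrast at age 4 via the fitted covariance
            x_m = models._prediction_row(4.0, "male", fit, "reference")
            x_f = models._prediction_row(4.0, "female", fit, "reference")
            d = x_m - x_f
            se = np.sqrt(d @ fit.fe_cov @ d)
            hits += abs(diff - 10.0) <= 1.96 * se
        assert hits >= int(0.84 * n_rep)

    def test_missing_outcome_column_rejected(self):
        cohort, _ = synth.simulate_cohort(synth.CohortSimParams(n_children=25, seed=3))
        with pytest.raises(ValueError, match="outcome"):
            models.fit_lmm(cohort, "nonexistent", SPEC)

    def test_covariate_adjustment_runs(self):
        cohort, _ = synth.simulate_cohort(synth.CohortSimParams(n_children=60, seed=4))
        fit = models.fit_lmm(cohort, "sedentary", SPEC)
        assert fit.converged
        assert any(t.startswith("maternal_work[") for t in fit.term_names)


class TestFitGlmm:
    def _adherence_frame(self, n, seed, b0=2.0, b1=-0.5, sd_u=0.8):
        rng = np.random.default_rng(seed)
        age1 = rng.uniform(2, 5, n)
        gap = rng.uniform(1.5, 2.5, n)
        u = rng.normal(0, sd_u, n)
        rows = []
        for i in range(n):
            for w, a in enumerate((age1[i], age1[i] + gap[i])):
                pr = expit(b0 + b1 * a + u[i])
                rows.append(
                    {"child_id": f"C{i}", "sex": "male" if i % 2 else "female",
                     "wave": w + 1, "age_years": a, "meets": int(rng.random() < pr)}
                )
        return pd.DataFrame(rows), b1

    def test_constant_outcome_flagged_as_separation(self):
        df, _ = self._adherence_frame(60, 0)
        df["meets"] = 1
        fit = models.fit_glmm(df, "meets", SPEC)
        assert not fit.converged
        assert "separation" in fit.notes
        assert np.isnan(fit.fe_params).all()
        with pytest.raises(ValueError, match="converge"):
            models.marginal_means(fit)

    def test_linear_logit_age_slope_recovered(self):
        df, b1 = self._adherence_frame(800, 7)
        fit = models.fit_glmm(df, "meets", SPEC)
        assert fit.converged
        i = fit.term_index("age")
        se = np.sqrt(fit.fe_cov[i, i])
        assert abs(fit.fe_params[i] - b1) < 2 * se

    def test_predicted_probabilities_in_unit_interval(self):
        df, _ = self._adherence_frame(200, 3)
        fit = models.fit_glmm(df, "meets", SPEC)
        mm = models.marginal_means(fit)
        assert ((mm.grid["estimate"] > 0) & (mm.grid["estimate"] < 1)).all()
        assert ((mm.grid["lo95"] <= mm.grid["estimate"])
                & (mm.grid["estimate"] <= mm.grid["hi95"])).all()

    def test_nonbinary_outcome_rejected(self):
        df, _ = self._adherence_frame(30, 1)
        df["meets"] = 2.0
        with pytest.raises(ValueError, match="binary"):
            models.fit_glmm(df, "meets", SPEC)

    def test_matches_glmer_oracle(self):
        """Fitted probability curve and random-intercept SD agree with
        lme4::glmer (adaptive Gauss-Hermite, nAGQ=25) on the same data."""
        df, _ = self._adherence_frame(150, 11)
        fit = models.fit_glmm(df, "meets", SPEC)
        X, names, _ = models.build_design(df, SPEC, ())
        d = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        d["meets"] = df["meets"].values
        d["gid"] = df["child_id"].values
        import tempfile, os

        with tempfile.TemporaryDirectory() as td:
            csv = os.path.join(td, "d.csv")
            d.to_csv(csv, index=False)
            rhs = "+".join(f"x{i}" for i in range(1, X.shape[1]))
            rcode = (
                "suppressMessages(library(lme4));"
                f"d <- read.csv('{csv}');"
                f"m <- glmer(meets ~ {rhs} + (1|gid), data=d, family=binomial, nAGQ=25);"
                "cat(fixef(m), sqrt(unlist(VarCorr(m))), sep=',')"
            )
            out = subprocess.run(
                ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300
            )
        assert out.returncode == 0, out.stderr
        vals = np.array([float(v) for v in out.stdout.strip().split(",")])
        beta_r, sigma_r = vals[:-1], vals[-1]
        assert np.sqrt(fit.random_intercept_var) == pytest.approx(sigma_r, abs=0.05)
        grid = np.linspace(2, 7, 11)
        basis = models.rcs_basis(grid, SPEC)
        Xg = np.column_stack(
            [np.ones(grid.size), np.zeros(grid.size), basis, basis * 0.0]
        )
        np.testing.assert_allclose(
            expit(Xg @ fit.fe_params), expit(Xg @ beta_r), atol=0.02
        )


class TestMarginalMeans:
    def test_ci_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (150, 600):
            cohort, _ = synth.simulate_cohort(synth.CohortSimParams(n_children=n, seed=13))
            fit = models.fit_lmm(cohort, "total_pa", SPEC, covariates=())
            mm = models.marginal_means(fit)
            widths[n] = (mm.grid["hi95"] - mm.grid["lo95"]).to_numpy()
        assert (widths[600] < widths[150]).all()

    def test_composite_identity_on_noise_free_data(self):
        """Marginal total PA equals marginal LPA + marginal energetic play
        when the outcomes satisfy the identity exactly by construction."""
        p = synth.CohortSimParams(
            n_children=80, residual_sd=0.0, random_intercept_sd=0.0, seed=5
        )
        cohort, _ = synth.simulate_cohort(p)
        mms = {
            out: models.marginal_means(
                models.fit_lmm(cohort, out, SPEC, covariates=())
            )
            for out in ("total_pa", "lpa", "energetic_play")
        }
        for age in (2, 3, 4, 5, 6, 7):
            for sex in ("male", "female"):
                total = mms["total_pa"].at(age, sex).estimate
                parts = mms["lpa"].at(age, sex).estimate + mms["energetic_play"].at(age, sex).estimate
                assert total == pytest.approx(parts, abs=1e-6)

    def test_extrapolation_warning_beyond_knots(self):
        cohort, _ = synth.simulate_cohort(synth.CohortSimParams(n_children=40, seed=6))
        fit = models.fit_lmm(cohort, "total_pa", SPEC, covariates=())
        mm = models.marginal_means(fit, ages=(1.9, 4.0, 7.5))
        assert any("1.9" in w for w in mm.warnings)
        assert any("7.5" in w for w in mm.warnings)

    def test_population_policy_close_to_reference_when_effects_null(self):
        cohort, _ = synth.simulate_cohort(synth.CohortSimParams(n_children=150, seed=8))
        fit = models.fit_lmm(cohort, "total_pa", SPEC,
                             covariates=("season", "dwelling"))
        ref = models.marginal_means(fit, policy="reference")
        pop = models.marginal_means(fit, policy="population")
        # covariates have no true effect, so the two policies agree closely
        np.testing.assert_allclose(
            ref.grid["estimate"], pop.grid["estimate"], atol=5.0
        )


class TestWaldTest:
    def test_single_term_equals_z_test(self):
        cohort, _ = synth.simulate_cohort(synth.CohortSimParams(n_children=100, seed=10))
        fit = models.fit_lmm(cohort, "total_pa", SPEC, covariates=())
        i = fit.term_index("sex_male")
        z = fit.fe_params[i] / np.sqrt(fit.fe_cov[i, i])
        p_z = 2 * stats.norm.sf(abs(z))
        test = models.wald_joint_test(fit, ["sex_male"])
        assert test.df == 1
        assert test.p_value == pytest.approx(p_z, rel=1e-10)

    def test_strong_interaction_detected(self):
        p = synth.CohortSimParams(n_children=400, sex_offset_interaction=8.0, seed=12)
        cohort, _ = synth.simulate_cohort(p)
        fit = models.fit_lmm(cohort, "total_pa", SPEC, covariates=())
        test = models.wald_joint_test(fit, models.interaction_terms(fit))
        assert test.p_value < 0.001

    def test_empty_block_rejected(self):
        cohort, _ = synth.simulate_cohort(synth.CohortSimParams(n_children=30, seed=2))
        fit = models.fit_lmm(cohort, "total_pa", SPEC, covariates=())
        with pytest.raises(ValueError, match="non-empty"):
            models.wald_joint_test(fit, [])


class TestUtilities:
    def test_cohens_d_study_design_value(self):
        es = models.cohens_d(5.0, 42.0)
        assert es.value == pytest.approx(5 / 42)
        assert es.rounded == 0.12

    @pytest.mark.parametrize("delta,sd,expected", [(0.0, 42.0, 0.0), (42.0, 42.0, 1.0)])
    def test_cohens_d_simple_cases(self, delta, sd, expected):
        assert models.cohens_d(delta, sd).value == pytest.approx(expected)

    def test_cohens_d_invalid_sd(self):
        with pytest.raises(ValueError):
            models.cohens_d(5.0, 0.0)

    def test_sum_composites_printed_means(self):
        boys = models.sum_composites(lpa=320.7, walk=15.2, run=2.0, mv_act_g=17.4)
        assert boys["energetic_play"] == pytest.approx(34.6, abs=0.11)
        assert boys["total_pa"] == pytest.approx(355.4, abs=0.11)
        zeros = models.sum_composites(lpa=0, walk=0, run=0, mv_act_g=0)
        assert zeros["total_pa"] == 0.0

    def test_sum_composites_negative_rejected(self):
        with pytest.raises(ValueError):
            models.sum_composites(lpa=-1, walk=0, run=0, mv_act_g=0)

    def test_power_monotone_in_n_and_effect(self):
        assert models.power_two_sample(5, 42, 400) > models.power_two_sample(5, 42, 100)
        assert models.power_two_sample(10, 42, 100) > models.power_two_sample(5, 42, 100)
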