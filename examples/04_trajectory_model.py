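"""Fit developmental trajectories with a spline mixed model.

Simulates a two-wave cohort with a known peaked total-PA curve, fits the
linear mixed model (sex, restricted cubic spline in age with four knots,
age-by-sex interaction, child random intercept, REML), and prints marginal
means over ages 2-7 with 95% CIs plus the joint Wald test of the
interaction.
"""

from actitraj import models, synth

cohort, truth = synth.simulate_cohort(synth.CohortSimParams(n_children=400, seed=7))
print(f"cohort: {len(cohort)} child-days, {cohort['child_id'].nunique()} children")

spec = models.SplineSpec(knots=synth.GENERATOR_KNOTS)
fit = models.fit_lmm(cohort, "total_pa", spec, covariates=())
print(f"fit: {fit.method}, converged={fit.converged}, "
      f"random-intercept SD {fit.random_intercept_var**0.5:.1f} min "
      f"(truth 20), residual SD {fit.residual_var**0.5:.1f} min (truth 30)")

mm = models.marginal_means(fit)
print("\nmarginal mean total PA (min/day), girls:")
for age in range(2, 8):
    g = mm.at(age, "female")
    tr = float(truth.mean_outcome("total_pa", age, "female"))
    print(f"  age {age}: {g.estimate:6.1f} ({g.lo95:6.1f}, {g.hi95:6.1f})"
          f"   generator truth {tr:6.1f}")

test = models.wald_joint_test(fit, models.interaction_terms(fit))
print(f"\nage-by-sex interaction: chi2({test.df}) = {test.statistic:.2f}, "
      f"p = {test.p_value:.3f} (generator has no interaction)")
print("\nThe curve peaks near age five by construction; the spline recovers"
      "\nit and the interaction test should usually be non-significant.")
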