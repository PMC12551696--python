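"""Recover the life-course effect with time-resolved MR, and show how the
two naive Wald-ratio implementations fail at old ages.

The observed instrument effect on outcome at age T accumulates the
instrument-exposure effect beta_G(t) over all t <= T; dividing it by a
constant (or even by beta_G(T)) therefore biases the estimate wherever
beta_G truly varies.  Time-resolved MR instead takes the Wald ratio of the
yearly *gradients* and re-integrates.
"""

import chronomr as cm
from chronomr.presets import validation_config

config = validation_config(n=100_000, seed=2)
cohort = cm.simulate_cohort(config)

beta = cm.fit_beta_quartic(cohort, covariates=["covar"])
beta_const = cm.fit_beta_constant(cohort, covariates=["covar"])

aalen_fit = cm.fit_aalen(cohort, ["instrument", "covar"], max_follow_age=80, seed=2)
increments = cm.yearly_increments(aalen_fit, "instrument")
series = cm.effect_series(increments, beta)

naive1 = cm.naive_wald_constant(increments, float(beta_const.coefficients[0]))
naive2 = cm.naive_wald_timevarying(increments, beta)

lo, hi = series.ci_mid()
truth = cm.true_cumulative_effect(config, series.years.astype(float))

print("cumulative effect of a 1-unit sustained exposure (hazard diff / year):")
print(f"{'T':>3} {'truth':>10} {'time-resolved':>14} {'95% CI':>22} "
      f"{'naive const':>12} {'naive b(T)':>11}")
for T in (40, 50, 60, 70, 80):
    i = T - 1
    print(
        f"{T:>3} {truth[i]:>10.2e} {series.Gamma_mid[i]:>14.2e} "
        f"[{lo[i]:>9.2e}, {hi[i]:>9.2e}] {naive1[i]:>12.2e} {naive2[i]:>11.2e}"
    )

print("\nAt T=80 the time-resolved estimate brackets the truth, while the")
print("time-averaged naive ratio underestimates and the beta_G(T)-only naive")
print("ratio overestimates it severalfold (beta_G declines with age).")
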