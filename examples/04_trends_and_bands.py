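"""Smoothed effect trends with parametric-bootstrap confidence bands.

Two smoothers on the yearly cumulative-effect series: the raised-cosine
kernel local-linear slope (the momentaneous effect averaged over a 10-year
window) and the Hodrick-Prescott trend of the cumulative effect itself
(penalty 50).  Bands come from 10,000 parametric bootstrap resamples of the
pointwise noise.
"""

import chronomr as cm
from chronomr.presets import validation_config

config = validation_config(n=100_000, seed=4)
cohort = cm.simulate_cohort(config)
beta = cm.fit_beta_quartic(cohort, covariates=["covar"])
afit = cm.fit_aalen(cohort, ["instrument", "covar"], max_follow_age=80, seed=4)
series = cm.effect_series(cm.yearly_increments(afit, "instrument"), beta)

ages = series.years.astype(float)

hp, hp_lo, hp_hi = cm.bootstrap_trend_bands(
    ages, series.Gamma_mid, series.var_Gamma_mid,
    lambda y: cm.hp_filter(y, 50.0), n_boot=10_000, seed=4,
)
gb, gb_lo, gb_hi = cm.bootstrap_trend_bands(
    ages, series.Gamma_mid, series.var_Gamma_mid,
    lambda y: cm.local_slope_series(ages, y, ages, 10.0), n_boot=10_000, seed=5,
)

print("age   HP trend of Gamma [95% band]        kernel gamma_bar [95% band]")
for T in (45, 55, 65, 75):
    i = T - 1
    print(
        f"{T:>3}  {hp[i]:>9.2e} [{hp_lo[i]:>9.2e},{hp_hi[i]:>9.2e}]  "
        f"{gb[i]:>9.2e} [{gb_lo[i]:>9.2e},{gb_hi[i]:>9.2e}]"
    )

c = config.gamma_scale
print("\ntrue gamma(t) = c t^4 at the same ages for comparison:")
print("      " + "  ".join(f"{c*T**4:.2e}" for T in (45, 55, 65, 75)))
print("\nThe kernel slope tracks the 10-year windowed average of gamma(t);")
print("the HP trend smooths Gamma itself. Bands widen with age because the")
print("instrument effect beta_G(t) weakens, inflating the Wald-ratio noise.")
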