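# Methods

This note records the statistical model behind `chronomr`, the conventions
and defaults the implementation fixes, and what the synthetic validation
scenario does and does not establish.

## Estimand and identification

Let x(t) be a continuous exposure and let υ(t) denote the *gradient* of the
hazard rate Υ(t), so that Υ(T) = ∫₀ᵀ υ(t) dt + C₀.  The structural model is
additive in both equations:

- latent outcome gradient: υ(t) = γ₀(t) + γ(t)·x(t) + (confounder and
  covariate terms) + error,
- exposure: x(t) = β₀(t) + β_G(t)·G + (confounder and covariate terms) + error,

with G a genetic instrument fixed at conception.  The estimand is the
cumulative (life-course) effect Γ(T) = ∫₀ᵀ γ(t) dt — the hazard-rate
difference at age T between two exposure trajectories one unit apart at all
ages — and its gradient γ(t), the momentaneous effect.

Substituting the exposure equation into the hazard gives the observed
instrument effect on the hazard at age T as Η(T) = ∫₀ᵀ γ(t) β_G(t) dt.
Because Η accumulates β_G over all past ages, Γ(T) ≠ Η(T)/β_G(T); instead
γ(t) = Η̇(t)/β_G(t) identifies the momentaneous effect (a Wald ratio of time
gradients), and Γ follows by re-integration.  The derivation assumes a
prompt change in exposure produces an instant, irreversible change in the
latent outcome; delayed-response generalizations are out of scope.

## Discrete-time implementation

All analysis lives on a yearly grid: bins (k−1, k], midpoints k−½,
Δt = 1 year.

**Aalen stage.**  The hazard λ(t|x) = b₀(t) + Σ b_m(t)·x_m is estimated via
the counting-process least-squares estimator of the cumulative coefficients
B̂_m(t).  Integer event ages are jittered uniformly into their year so each
event time is unique; at an event with covariate row x_e and at-risk Gram
matrix A = X_R'X_R, the increment is v = A⁻¹x_e and the variance increment
is v v' (single event per time).  The implementation orders individuals by
exit time and uses suffix sums of covariate outer products plus batched
solves, so a fit is O(n·p²) memory and a few hundred milliseconds at
n = 10⁵.  Events past the administrative cutoff (default 76 years, matching
register practice; 80 in the validation scenario) are treated as censored
there.  No delayed entry by default — register follow-up runs from birth —
but an entry-age column enables left truncation.

The yearly level Η̂(t_k) = B̂_G(t_ψ) − B̂_G(t_χ), the difference between the
cumulative coefficient at the last event of year k and of year k−1,
estimates the instrument effect on the hazard *at* age k, since B̂_G
integrates that effect over time.  Its variance σ_k² is the matching
difference of cumulative variances (increments are uncorrelated).  Years
without events contribute zero.

**Wald stage.**  γ̂(t_{k−½}) = (Η̂(t_k) − Η̂(t_{k−1}))/β_G(t_{k−½}) with
Η̂(t₀) = 0 and Var[γ̂] = (σ_k² + σ_{k−1}²)/β_G²(t_{k−½}).  The midpoint rule
Γ̂(t_k) = Σ_{i≤k} γ̂(t_{i−½}) telescopes exactly to Η̂(t_k)/β_G for constant
β_G, and its variance is approximated by σ_k²/β_G²(t_k) (the ratio
telescopes when β_G varies slowly).  The trapezoid rule, used for
presentation, carries weights (¼ + ½, 1, …, 1, ½) from the origin and is
evaluated at midpoints t_{k−½} — comparisons against a truth curve must use
that midpoint grid, or a spurious half-year offset appears.  Its variance
uses the full three-term expression (with the k = 1, 2 special cases) and a
simplified σ_k²/2β_G²(t_k) variant; the two agree within 12.5% for slowly
varying σ.  Downstream smoothing always consumes the midpoint series, whose
pointwise errors are uncorrelated across years.

One formula-level inconsistency is kept deliberately rather than resolved:
γ̂ divides by β_G at midpoints while the Γ̂ variance divides at integer ages;
at yearly resolution the difference is far below the Monte-Carlo noise.

**Instrument stage.**  β_G(t) is fitted by OLS of the exposure on
instrument, instrument×t and instrument×t⁴ (quartic) or instrument×t
(linear), with additive covariates, restricted to individuals event free at
assessment; age enters in raw years.  Pointwise variance is the
delta-method quadratic form g'Σg, g = (1, t, t⁴).  A weak-instrument floor
(default |β_G| ≥ 0.01 exposure-SD per instrument unit on the analysis grid)
makes the division refuse loudly instead of amplifying noise; the linear
model is the documented fallback when the quartic extrapolation crosses
zero.  Instrument×covariate interactions are out of scope.

**Trend stage.**  The smoothed momentaneous effect γ̄(T) is the slope of a
weighted linear fit of Γ̂ around T with raised-cosine weights
K(u) = (cos(πu/b)+1)/2 on |u| ≤ b; b = 10 years is the full duration at
half maximum (K(±b/2) = ½) and sets the temporal resolution.  Near the grid
ends the kernel is truncated (asymmetric); the local-linear form stays
first-order unbiased there and no further boundary correction is applied.
The trend of Γ̂ uses a Hodrick–Prescott filter with λ = 50, implemented as a
direct solve of (I + λD′D)τ = y so that thousands of bootstrap series can
be filtered as one matrix solve (statsmodels' filter is the independent
cross-check in the tests).  Confidence bands are percentile intervals over
a parametric bootstrap (default 10,000 samples): Γ̂(t_k) + ε_k with
independent ε_k ~ N(0, σ_k²/β_G²(t_k)), trend refit per sample.  Only the
Γ̂ noise is resampled, not the upstream fits.  A basic resampling bootstrap
utility is provided for descriptive stratum statistics.

**Preparation stages.**  Exposure z-transformation is per (sex × integer
age) stratum with the tails pooled at ≤40 and ≥70 and the n−1 SD
convention.  Cross-fitted polygenic scores: each half-cohort is scored with
weights discovered in the other half, standardized within half, then
remerged; missing dosages are imputed as twice the allele frequency of the
scoring sample.  Steiger filtering uses the two-dependent-overlapping-
correlations z statistic on Fisher-transformed correlations, one-tailed for
ρ_gx > ρ_gy, with ρ_xy estimated as the median of ρ_gy/ρ_gx and
Benjamini–Hochberg FDR control at 0.05; for binary outcomes the per-SNP
outcome correlation is the point-biserial correlation with the
event-by-cutoff indicator (whether the original protocol used that
indicator or a residual-type outcome is not stated; the convention here is
documented and configurable).  The statistic's variance factor degenerates
for extreme correlation configurations (f·ρ̄² ≥ 1); such inputs are
rejected explicitly.

**Selection correction.**  The probit resampling correction appends
reference individuals (assessed below 45 y) to each age stratum with
probability Φ(d_i − μ_k), d_i the globally standardized exposure, until the
stratum mean score equals the original mean plus the linear-trend offset
m_k anchored at age 40, within ε (default 0.005 score-SD; any small positive tolerance is
admissible).  μ_k is found by table search
on a grid spanning [−4, 8] in steps of 0.01 plus a no-append option; the
search prefers the fewest appended individuals meeting the tolerance.  One
uniform draw per reference individual per stratum makes the selection
nested and monotone in μ, reducing the search to a sort plus suffix sums.
The correction is relative — it rectifies the slope of the mean score over
ages 40–70, never the absolute level — and can only raise stratum means
(it appends high-exposure individuals), which is the direction the
participation bias acts in.

## The synthetic validation scenario

The generator emulates the validation design: dichotomous Bernoulli(0.5)
carrier instrument (Binomial(2, f) dosages in multi-SNP mode); quartic
instrument profile β_G(t) = 0.3 − 9×10⁻⁴t − 4×10⁻⁹t⁴; momentaneous effect
γ(t) = c_γ·t⁴ so Γ(T) = c_γT⁵/5; a Gamma(2, 0.5) confounder and a standard
normal covariate with time-dependent coefficients on both equations;
negative-binomial onset realized as a mean-one gamma frailty multiplying
yearly Poisson counts on the cumulative-hazard increments, first positive
count = onset.  Yearly hazards are floored at zero and the clipped
person-year fraction is reported (≈2–3% under the default scenario; >10%
warns).

The scenario leaves the confounder/covariate coefficient profiles,
the error variances, the effect magnitude c_γ and the baseline-hazard shape
unpinned; they are fixed here once, as study conditions:

- mild low-order polynomial profiles with confounding of the same order as
  the instrument effect (see `simulate.py` defaults);
- exposure noise SD 0.55, giving total exposure SD ≈ 0.6 and an instrument
  R² of ≈4% — the strength of a realistic polygenic instrument for an
  anthropometric trait, and enough that β̂_G(80) (where the quartic dips to
  0.064) is estimated with usable precision;
- c_γ = 2.3×10⁻¹¹, i.e. Γ(80) ≈ 1.5×10⁻² hazard difference per year per
  sustained exposure unit — a magnitude typical of additive-hazard effects for common adult-onset
  disease —
  against a baseline hazard of ≈10⁻² per year at 80;
- baseline hazard gradient ∝ t⁶ (hazard ∝ t⁷: adult-onset incidence
  concentrated at old age) plus a small constant offset 2×10⁻⁴/y, which
  keeps young-age hazards positive; the gradient scale is what
  `calibrate_baseline` bisects on to hit a target prevalence;
- frailty shape 20 (variance 0.05): overdispersed but close enough to
  Poisson that frailty-induced attenuation of the marginal additive effect
  is negligible relative to Monte-Carlo error;
- assessment ages uniform on 20–79 years, wider than a typical recruitment
  window, so the quartic fit interpolates rather than extrapolates across
  the full analysis range and its age-0 intercept is well conditioned.

The low/high prevalence variants (3% and 30% by age 80) rescale every term
of the hazard gradient by a common factor before recalibration, preserving
the positivity structure of the main scenario.  Event ages are recorded
with the floor convention (onset in bin k ⇒ integer age k−1), which aligns
the generator's bins with the Aalen analysis bins exactly; with that
alignment the midpoint-rule Γ̂(t_k) estimates the discrete truth
Σ_{i≤k} γ(i−½), which differs from c_γT⁵/5 by ~0.01%.

What the generator does *not* emulate: linkage disequilibrium, genotyping
error, relatedness, sex-specific generative differences (the sex column is
carried but inert), measurement error distinct from biological noise, and
time-varying confounder values (profiles vary; individual draws are fixed
at birth).  Passing tests therefore demonstrate correctness of the
estimator under its own assumptions, not robustness to those real-data
complications.

## Validation quantities and problem sizes

The replicate study behind the headline validation runs 300 cohorts of
n = 10⁵ and checks that the mean recovered Γ̂ at ages 40/60/80 sits within
three Monte-Carlo standard errors of the truth while both naive Wald
comparators carry at least three-fold larger absolute bias at 80 (the
time-averaged ratio sits ≈30% low, the β_G(T)-only ratio ≈130% high —
these are analytic consequences of the declining quartic, not tuning).
Power-law exponents are measured as OLS slopes of log Γ̂(T) against log T
over T ∈ [50, 80] (truth 5) and of the log kernel trend over [50, 75]
(truth 4).  A single desk-scale cohort gives a noisy pointwise curve, so
the acceptance script measures the exponents on the Γ̂ curve averaged over
20 replicates of n = 2×10⁵ and the instrument intercept over 8 replicates —
the scaled-down analog of a repeated-simulation design; the replication
counts are stated in the script.  Pointwise 95% CI calibration and the
92–98% bootstrap-band coverage are checked at reduced n in the test suite.

## Known limitations

- Var[Γ̂] treats β̂_G as fixed; at ages where β_G is small the neglected
  denominator noise widens the true sampling distribution (visible at
  T = 80 in the validation scenario); the bands are therefore mildly
  anticonservative exactly where the instrument is weakest.
- The hazard floor mildly distorts the additive model in the clipped tail;
  under the default scenario the induced bias is below Monte-Carlo error,
  but configurations with warn-level clipping should not be trusted for
  unbiasedness checks.
- The trapezoid variance at early ages relies on the explicit small-k
  special cases and is approximate.
- The selection correction can only rectify *declining* score trends, and
  reuses participants (duplicates are flagged, not reweighted).
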