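"""Synthetic time-to-event cohorts with an age-varying genetic instrument.

The generator produces the validation scenario for time-resolved Mendelian
randomization: a dichotomous genetic instrument whose effect on a continuous
exposure follows a quartic polynomial in age, a momentaneous exposure effect
on the latent disease process that grows as a power law ``gamma(t) = c_g t^4``
(so the life-course effect is proportional to ``T^5``), a gamma-distributed
confounder and an extra covariate with time-dependent coefficients on both
exposure and outcome, and disease onset driven by a negative-binomial count
process (gamma frailty mixing yearly Poisson counts on the cumulative-hazard
increments).

Time is discretized in yearly bins ``(k-1, k]`` with all time-dependent
profiles evaluated at bin midpoints ``k - 1/2``.  The recorded integer
``event_age`` is the age at onset under the floor convention (an event in bin
``k`` has ``event_age = k - 1``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate


def quartic_profile(t: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Evaluate the quartic instrument-effect curve ``a + b t + c t^4``."""
    t = np.asarray(t, dtype=float)
    return a + b * t + c * t**4


def default_confounder_exposure_profile(t):
    """Coefficient of the (centered) confounder on exposure; mild increase with age."""
    return 0.15 + 5.0e-4 * np.asarray(t, dtype=float)


def default_covariate_exposure_profile(t):
    """Coefficient of the extra covariate on exposure; mild decrease with age."""
    return 0.10 - 2.5e-4 * np.asarray(t, dtype=float)


def default_confounder_outcome_profile(t):
    """Coefficient of the (centered) confounder on the latent hazard gradient."""
    return 1.0e-4 * (np.asarray(t, dtype=float) / 80.0) ** 4


def default_covariate_outcome_profile(t):
    """Coefficient of the extra covariate on the latent hazard gradient."""
    return 5.0e-5 * (np.asarray(t, dtype=float) / 80.0) ** 2


@dataclass
class SimulationConfig:
    """Parameters of the validation-scenario generative model.

    Attributes
    ----------
    n_individuals
        Cohort size.
    max_age
        End of simulated follow-up in years; individuals without an event are
        censored at this age.
    instrument_freq
        Carrier frequency of the dichotomous (Bernoulli 0/1) instrument.
    beta_g_coeffs
        ``(a, b, c)`` of the instrument effect on exposure
        ``beta_G(t) = a + b t + c t^4`` (exposure units per instrument unit).
    gamma_scale
        Scale ``c_g`` of the momentaneous exposure effect
        ``gamma(t) = c_g t^4`` (hazard-rate change per year, per exposure
        unit-year); ignored when ``gamma_profile`` is given.
    gamma_profile
        Optional general momentaneous-effect profile ``gamma(t)``.
    confounder_shape, confounder_scale
        Gamma-distribution parameters of the individual confounder.
    confounder_exposure_profile, covariate_exposure_profile
        Time-dependent coefficients of confounder/covariate on exposure.
    confounder_outcome_profile, covariate_outcome_profile
        Time-dependent coefficients on the latent hazard gradient.
    baseline_hazard
        Scale ``g0`` of the baseline hazard gradient
        ``gamma0(t) = g0 (t/max_age)**baseline_power`` — the knob the
        prevalence calibration turns.
    baseline_power
        Power of the baseline hazard gradient (default 6: incidence strongly
        concentrated at old age, as for adult-onset disease).
    hazard_offset
        Constant ``C0 >= 0`` added to the hazard rate at all ages.
    frailty_dispersion
        Shape of the mean-one gamma frailty mixing the yearly Poisson counts
        (frailty variance is ``1/frailty_dispersion``); ``inf`` recovers a
        pure Poisson onset process.
    noise_sd_exposure, noise_sd_outcome
        SDs of the yearly i.i.d. errors on exposure and hazard gradient.
    assessment_age_range
        Inclusive integer range the age at assessment is drawn from.
    seed
        Seed; fixing it reproduces the cohort bit for bit.
    """

    n_individuals: int = 100_000
    max_age: int = 80
    instrument_freq: float = 0.5
    beta_g_coeffs: tuple[float, float, float] = (0.3, -9.0e-4, -4.0e-9)
    gamma_scale: float = 2.3e-11
    gamma_profile: Callable[[np.ndarray], np.ndarray] | None = None
    confounder_shape: float = 2.0
    confounder_scale: float = 0.5
    confounder_exposure_profile: Callable = field(
        default=default_confounder_exposure_profile
    )
    covariate_exposure_profile: Callable = field(
        default=default_covariate_exposure_profile
    )
    confounder_outcome_profile: Callable = field(
        default=default_confounder_outcome_profile
    )
    covariate_outcome_profile: Callable = field(
        default=default_covariate_outcome_profile
    )
    baseline_hazard: float = 1.07e-3
    baseline_power: float = 6.0
    hazard_offset: float = 2.0e-4
    frailty_dispersion: float = 20.0
    noise_sd_exposure: float = 0.55
    noise_sd_outcome: float = 0.0
    assessment_age_range: tuple[int, int] = (20, 79)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.instrument_freq < 1.0):
            raise ValueError("instrument_freq must lie in (0, 1)")
        if self.max_age <= 0:
            raise ValueError("max_age must be positive")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be non-negative")
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")

    def gamma(self, t) -> np.ndarray:
        """Momentaneous exposure effect gamma(t)."""
        t = np.asarray(t, dtype=float)
        if self.gamma_profile is not None:
            return np.asarray(self.gamma_profile(t), dtype=float)
        return self.gamma_scale * t**4

    def beta_g(self, t) -> np.ndarray:
        """Instrument effect on exposure beta_G(t)."""
        return quartic_profile(t, *self.beta_g_coeffs)


def true_cumulative_effect(config: SimulationConfig, T) -> np.ndarray | float:
    """Life-course effect ``Gamma(T) = int_0^T gamma(t) dt`` of the generator.

    Closed form ``c_g T^5 / 5`` for the default power-law profile; adaptive
    quadrature for a general ``gamma_profile``.  This is the oracle every
    recovery test compares against.
    """
    T_arr = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(T_arr < 0) or np.any(T_arr > config.max_age):
        raise ValueError("T must lie in [0, max_age]")
    if config.gamma_profile is None:
        out = config.gamma_scale * T_arr**5 / 5.0
    else:
        out = np.array(
            [integrate.quad(config.gamma_profile, 0.0, float(u))[0] for u in T_arr]
        )
    return out if np.ndim(T) else float(out[0])


def _event_thresholds(
    n: int, frailty_dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative-hazard thresholds of the frailty-mixed yearly count process.

    Given gamma frailty ``Z`` the yearly counts are Poisson(Z * dY_k); the
    first bin with a positive count is the onset bin.  Equivalently the onset
    bin is the first k whose cumulative clipped hazard reaches Exp(1)/Z.
    """
    if np.isfinite(frailty_dispersion):
        z = rng.gamma(frailty_dispersion, 1.0 / frailty_dispersion, n)
    else:
        z = np.ones(n)
    return rng.exponential(size=n) / z


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a cohort under the validation model.

    Returns a DataFrame with one row per individual and columns ``id``,
    ``sex``, ``instrument``, ``exposure_raw``, ``covar``,
    ``age_at_assessment``, ``event_age`` (integer onset age, NaN if none) and
    ``censor_age``.  The fraction of person-year hazard increments clipped at
    zero is recorded in ``df.attrs["clip_fraction"]``; a clipping fraction
    above 10% triggers a warning (implausible configuration).
    """
    profiles = [(config.instrument_freq, config.beta_g)]
    return _simulate(config, instrument_profiles=profiles, dichotomous=True)


def simulate_multisnp_cohort(
    config: SimulationConfig,
    snp_profiles: Sequence[tuple[float, Callable]],
) -> pd.DataFrame:
    """Generate a cohort whose exposure is driven by several independent SNPs.

    ``snp_profiles`` is a sequence of ``(allele_freq, beta_j(t))`` pairs; each
    SNP contributes ``beta_j(t) * g_ij`` to the exposure with independent
    Binomial(2, freq) dosages.  A ``pgs`` column equal to the unweighted
    genotype sum is appended, alongside per-SNP ``snp{j}`` dosage columns.
    """
    if len(snp_profiles) < 2:
        raise ValueError("need at least 2 SNP profiles; use simulate_cohort for one")
    return _simulate(config, instrument_profiles=list(snp_profiles), dichotomous=False)


def _simulate(
    config: SimulationConfig,
    instrument_profiles: list[tuple[float, Callable]],
    dichotomous: bool,
) -> pd.DataFrame:
    n = config.n_individuals
    K = int(config.max_age)
    rng = np.random.default_rng(config.seed)

    # individual-level draws
    genos = []
    for freq, _ in instrument_profiles:
        if dichotomous:
            genos.append((rng.random(n) < freq).astype(float))
        else:
            genos.append(rng.binomial(2, freq, n).astype(float))
    u_raw = rng.gamma(config.confounder_shape, config.confounder_scale, n)
    u = u_raw - config.confounder_shape * config.confounder_scale  # centered
    zc = rng.standard_normal(n)
    sex = rng.integers(0, 2, n)
    lo, hi = config.assessment_age_range
    assess_age = rng.integers(lo, hi + 1, n)

    mids = np.arange(1, K + 1) - 0.5
    gamma_m = config.gamma(mids)
    base_m = config.baseline_hazard * (mids / K) ** config.baseline_power
    au_m = np.asarray(config.confounder_outcome_profile(mids), dtype=float)
    az_m = np.asarray(config.covariate_outcome_profile(mids), dtype=float)
    cux_m = np.asarray(config.confounder_exposure_profile(mids), dtype=float)
    czx_m = np.asarray(config.covariate_exposure_profile(mids), dtype=float)
    beta_m = [np.asarray(prof(mids), dtype=float) for _, prof in instrument_profiles]

    if not np.all(np.isfinite(base_m + au_m + az_m + cux_m + czx_m + gamma_m)):
        raise ValueError("non-finite hazard profile; mis-specified time profiles")

    threshold = _event_thresholds(n, config.frailty_dispersion, rng)

    # Year-by-year accumulation of the latent hazard.  The hazard rate in bin
    # k is Upsilon_i(k) = C0 + sum_{j<=k} upsilon_i(j-1/2), floored at zero;
    # upsilon is the latent gradient of the hazard (baseline + gamma*x +
    # confounder + covariate [+ noise]).
    grad = np.zeros(n)
    cum_hazard = np.zeros(n)
    event_bin = np.zeros(n, dtype=np.int64)  # 0 = no event
    clipped = 0
    sigx = config.noise_sd_exposure
    for k in range(1, K + 1):
        j = k - 1
        x_mid = u * cux_m[j] + zc * czx_m[j]
        for g, bm in zip(genos, beta_m):
            x_mid = x_mid + bm[j] * g
        if sigx > 0:
            x_mid = x_mid + sigx * rng.standard_normal(n)
        upsilon = base_m[j] + gamma_m[j] * x_mid + au_m[j] * u + az_m[j] * zc
        if config.noise_sd_outcome > 0:
            upsilon = upsilon + config.noise_sd_outcome * rng.standard_normal(n)
        grad += upsilon
        hazard_k = config.hazard_offset + grad
        neg = hazard_k < 0
        clipped += int(neg.sum())
        hazard_k = np.where(neg, 0.0, hazard_k)
        cum_hazard += hazard_k  # dt = 1 year
        newly = (event_bin == 0) & (cum_hazard >= threshold)
        event_bin[newly] = k

    clip_fraction = clipped / (n * K)
    if clip_fraction > 0.10:
        warnings.warn(
            f"{clip_fraction:.1%} of person-year hazard increments were clipped at "
            "zero; the configuration is implausible",
            RuntimeWarning,
            stacklevel=2,
        )

    # exposure measured at assessment (fresh yearly error draw)
    t_a = assess_age.astype(float)
    x_assess = (
        u * np.asarray(config.confounder_exposure_profile(t_a), dtype=float)
        + zc * np.asarray(config.covariate_exposure_profile(t_a), dtype=float)
    )
    for (freq, prof), g in zip(instrument_profiles, genos):
        x_assess = x_assess + np.asarray(prof(t_a), dtype=float) * g
    if sigx > 0:
        x_assess = x_assess + sigx * rng.standard_normal(n)

    event_age = np.where(event_bin > 0, event_bin - 1.0, np.nan)
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": sex,
            "instrument": genos[0] if dichotomous else np.sum(genos, axis=0),
            "exposure_raw": x_assess,
            "covar": zc,
            "age_at_assessment": assess_age,
            "event_age": event_age,
            "censor_age": float(K),
        }
    )
    if not dichotomous:
        for jj, g in enumerate(genos, start=1):
            df[f"snp{jj}"] = g
        df["pgs"] = np.sum(genos, axis=0)
    df.attrs["clip_fraction"] = clip_fraction
    df.attrs["config_seed"] = config.seed
    return df


def realized_prevalence(cohort: pd.DataFrame) -> float:
    """Fraction of individuals with an event during simulated follow-up."""
    return float(cohort["event_age"].notna().mean())


def calibrate_baseline(
    config: SimulationConfig,
    target_prevalence: float,
    n_calib: int = 100_000,
    tolerance: float = 0.005,
    max_iter: int = 40,
) -> SimulationConfig:
    """Calibrate ``baseline_hazard`` so prevalence by ``max_age`` hits a target.

    Bisection on the baseline-hazard scale against calibration cohorts of
    ``n_calib`` individuals drawn with a fixed seed (so realized prevalence is
    a deterministic, monotone function of the baseline during the search).
    Returns a copy of ``config`` with the calibrated baseline.

    Raises
    ------
    RuntimeError
        If no bracket exists (target unreachable with a non-negative hazard).
    """
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError("target_prevalence must lie in (0, 1)")

    calib_seed = (config.seed * 7919 + 17) % (2**31)

    def prev(b0: float) -> float:
        c = replace(
            config, n_individuals=n_calib, baseline_hazard=b0, seed=calib_seed
        )
        with warnings.catch_warnings():
            # the bracket search deliberately visits implausible baselines
            warnings.simplefilter("ignore", RuntimeWarning)
            return realized_prevalence(simulate_cohort(c))

    lo, hi = 0.0, max(config.baseline_hazard, 1e-6)
    p_hi = prev(hi)
    n_expand = 0
    while p_hi < target_prevalence:
        hi *= 2.0
        p_hi = prev(hi)
        n_expand += 1
        if n_expand > 30:
            raise RuntimeError("bisection bracket failure: target prevalence unreachable")
    p_lo = prev(lo)
    if p_lo > target_prevalence:
        raise RuntimeError(
            "bisection bracket failure: prevalence at zero baseline already "
            f"exceeds target ({p_lo:.3f} > {target_prevalence:.3f})"
        )

    b_mid = hi
    for _ in range(max_iter):
        b_mid = 0.5 * (lo + hi)
        p_mid = prev(b_mid)
        if abs(p_mid - target_prevalence) <= 0.25 * tolerance:
            break
        if p_mid < target_prevalence:
            lo = b_mid
        else:
            hi = b_mid
    return replace(config, baseline_hazard=b_mid)
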