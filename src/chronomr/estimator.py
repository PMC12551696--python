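"""The time-resolved Mendelian randomization estimator.

Given yearly instrument-effect levels on the hazard, ``H_hat(t_k)``, and a
fitted age-varying instrument effect on the exposure, ``beta_G(t)``, the
momentaneous effect of the exposure at the bin midpoint is the Wald ratio of
the finite-difference time gradient,

    gamma_hat(t_{k-1/2}) = (H_hat(t_k) - H_hat(t_{k-1})) / beta_G(t_{k-1/2}),

with ``H_hat(t_0) = 0``.  Summing the momentaneous effects (midpoint rule)
or trapezoid-weighting them gives the cumulative life-course effect
``Gamma_hat``.  Variances propagate from the yearly Aalen variances
``sigma_k^2``; because the ratio telescopes when ``beta_G`` varies slowly,
``Var[Gamma_hat(t_k)] ~ sigma_k^2 / beta_G^2(t_k)``.

Units: ``gamma`` is a hazard-rate change per year per exposure unit;
``Gamma`` is a hazard-rate difference per year per exposure unit sustained
since conception.

Two naive Wald comparators are included: dividing the hazard-level series by
a time-averaged constant effect, and dividing by ``beta_G(T)`` at the
evaluation age only.  Both ignore that the instrument effect on outcome at
age ``T`` accumulates ``beta_G(t)`` over all earlier ages, and are biased
whenever ``beta_G`` truly varies in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aalen import YearlyIncrements
from .instrument import InstrumentEffectFunction


class WeakInstrumentError(RuntimeError):
    """|beta_G| fell below the configured floor somewhere on the grid."""


def _check_floor(beta_vals: np.ndarray, ages: np.ndarray, floor: float) -> None:
    bad = np.abs(beta_vals) < floor
    if bad.any():
        offending = np.asarray(ages)[bad]
        raise WeakInstrumentError(
            f"|beta_G(t)| < {floor} at ages {offending[:8].tolist()}"
            f"{'...' if bad.sum() > 8 else ''}; refuse the Wald ratio — "
            "consider the linear instrument model"
        )


@dataclass
class EffectSeries:
    """Tidy per-year output of the time-resolved MR estimator.

    Grid ``years`` k = 1..K; midpoints ``k - 1/2``.  ``gamma_hat`` sits on
    midpoints; ``Gamma_mid`` on integer years; ``Gamma_trap`` on midpoints.
    """

    years: np.ndarray
    gamma_hat: np.ndarray
    var_gamma: np.ndarray
    Gamma_mid: np.ndarray
    var_Gamma_mid: np.ndarray
    Gamma_trap: np.ndarray
    var_Gamma_trap: np.ndarray
    alpha: float = 0.05

    @property
    def midpoints(self) -> np.ndarray:
        return self.years - 0.5

    def ci_mid(self) -> tuple[np.ndarray, np.ndarray]:
        return pointwise_ci(self.Gamma_mid, self.var_Gamma_mid, self.alpha)

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.ci_mid()
        return pd.DataFrame(
            {
                "year": self.years,
                "midpoint": self.midpoints,
                "gamma_hat": self.gamma_hat,
                "var_gamma": self.var_gamma,
                "Gamma_mid": self.Gamma_mid,
                "var_Gamma_mid": self.var_Gamma_mid,
                "ci_lo_mid": lo,
                "ci_hi_mid": hi,
                "Gamma_trap": self.Gamma_trap,
                "var_Gamma_trap": self.var_Gamma_trap,
            }
        )


def momentaneous_effects(
    incr: YearlyIncrements,
    beta: InstrumentEffectFunction,
    floor: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Momentaneous effects gamma_hat at midpoints and their variances.

    ``gamma_hat(t_{k-1/2}) = (H_hat(t_k) - H_hat(t_{k-1})) / beta_G(t_{k-1/2})``
    and ``Var = (sigma_k^2 + sigma_{k-1}^2) / beta_G^2(t_{k-1/2})``.
    """
    mids = incr.years - 0.5
    beta_mid = np.atleast_1d(beta(mids))
    _check_floor(beta_mid, mids, floor)
    H_prev = np.concatenate([[0.0], incr.H_hat[:-1]])
    s2_prev = np.concatenate([[0.0], incr.sigma2[:-1]])
    gamma = (incr.H_hat - H_prev) / beta_mid
    var_gamma = (incr.sigma2 + s2_prev) / beta_mid**2
    return gamma, var_gamma


def cumulative_midpoint(gamma: np.ndarray) -> np.ndarray:
    """Midpoint-rule cumulative effect: running sum of gamma_hat, Gamma(0)=0."""
    return np.cumsum(np.asarray(gamma, dtype=float))


def cumulative_trapezoid(gamma: np.ndarray) -> np.ndarray:
    """Trapezoid-rule cumulative effect at midpoints t_{k-1/2}.

    ``Gamma(t_{1/2}) = gamma_1/4`` (triangle from the origin); thereafter the
    trapezoid weights ``1/4 + 1/2, 1, ..., 1, 1/2`` apply, i.e.
    ``Gamma(t_{k-1/2}) = 3/4 g_1 + sum_{i=2}^{k-1} g_i + 1/2 g_k``.
    """
    g = np.asarray(gamma, dtype=float)
    out = np.empty(g.size)
    out[0] = g[0] / 4.0
    if g.size > 1:
        csum = np.cumsum(g)
        idx = np.arange(1, g.size)
        # 3/4 g_1 + sum over interior bins 2..k-1 + 1/2 g_k
        out[idx] = 0.75 * g[0] + (csum[idx - 1] - g[0]) + 0.5 * g[idx]
    return out


def variance_midpoint(
    incr: YearlyIncrements, beta: InstrumentEffectFunction, floor: float = 0.01
) -> np.ndarray:
    """Variance of the midpoint-rule cumulative effect:
    ``Var[Gamma_hat(t_k)] = sigma_k^2 / beta_G^2(t_k)``."""
    years = incr.years.astype(float)
    b = np.atleast_1d(beta(years))
    _check_floor(b, years, floor)
    return incr.sigma2 / b**2


def variance_trapezoid(
    incr: YearlyIncrements,
    beta: InstrumentEffectFunction,
    floor: float = 0.01,
    simplified: bool = False,
) -> np.ndarray:
    """Variance of the trapezoid-rule cumulative effect.

    Full form (interior k >= 3):
    ``sigma_1^2/(16 b^2(t_1)) + sigma_{k-1}^2/(4 b^2(t_{k-1}))
    + sigma_k^2/(4 b^2(t_k))`` with explicit k = 1, 2 special cases;
    the simplified large-k form is ``sigma_k^2 / (2 b^2(t_k))``.
    """
    years = incr.years.astype(float)
    b = np.atleast_1d(beta(years))
    _check_floor(b, years, floor)
    s2 = incr.sigma2
    if simplified:
        return s2 / (2.0 * b**2)
    out = np.empty_like(s2)
    out[0] = s2[0] / (16.0 * b[0] ** 2)
    if s2.size > 1:
        out[1] = s2[0] / (16.0 * b[0] ** 2) + s2[1] / (4.0 * b[1] ** 2)
    if s2.size > 2:
        k = np.arange(2, s2.size)
        out[2:] = (
            s2[0] / (16.0 * b[0] ** 2)
            + s2[k - 1] / (4.0 * b[k - 1] ** 2)
            + s2[k] / (4.0 * b[k] ** 2)
        )
    return out


def pointwise_ci(
    Gamma: np.ndarray, var: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric normal pointwise bands Gamma +/- z_{1-alpha/2} sqrt(var)."""
    var = np.asarray(var, dtype=float)
    if np.any(var < 0):
        raise ValueError("negative variance")
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    half = zq * np.sqrt(var)
    G = np.asarray(Gamma, dtype=float)
    return G - half, G + half


def effect_series(
    incr: YearlyIncrements,
    beta: InstrumentEffectFunction,
    floor: float = 0.01,
    alpha: float = 0.05,
) -> EffectSeries:
    """Full time-resolved MR output: momentaneous + cumulative effects,
    variances and pointwise CIs on the yearly grid."""
    gamma, var_gamma = momentaneous_effects(incr, beta, floor)
    return EffectSeries(
        years=incr.years.copy(),
        gamma_hat=gamma,
        var_gamma=var_gamma,
        Gamma_mid=cumulative_midpoint(gamma),
        var_Gamma_mid=variance_midpoint(incr, beta, floor),
        Gamma_trap=cumulative_trapezoid(gamma),
        var_Gamma_trap=variance_trapezoid(incr, beta, floor),
        alpha=alpha,
    )


def naive_wald_constant(incr: YearlyIncrements, beta_const: float) -> np.ndarray:
    """Naive comparator: hazard-level series divided by a constant,
    time-averaged instrument effect.  Biased when beta_G varies in time."""
    if beta_const == 0:
        raise ZeroDivisionError("constant instrument effect is zero")
    return incr.H_hat / beta_const


def naive_wald_timevarying(
    incr: YearlyIncrements, beta: InstrumentEffectFunction, floor: float = 0.01
) -> np.ndarray:
    """Naive comparator: hazard-level series divided by beta_G(T) at the
    evaluation age only — correct time dependence of the instrument, but the
    accumulation of past beta_G(t), t <= T, is not undone."""
    years = incr.years.astype(float)
    b = np.atleast_1d(beta(years))
    _check_floor(b, years, floor)
    return incr.H_hat / b
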