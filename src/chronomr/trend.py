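"""Trend extraction for the time-resolved effect series.

Two smoothers are provided, matching the two effect scales:

* a kernel-weighted local-linear regression of the cumulative effect whose
  fitted slope at the target age is the *smoothed momentaneous effect*
  ``gamma_bar(T)`` — the momentaneous effect averaged over a window whose
  width is set by the raised-cosine kernel's full duration at half maximum
  (FDHM) ``b``;
* a Hodrick-Prescott filter (penalty ``lambda``) for the trend of the
  cumulative effect itself.

Confidence bands for either trend come from a parametric bootstrap that
perturbs the cumulative-effect series with independent normal noise
``eps_k ~ N(0, sigma_k^2 / beta_G^2(t_k))`` and refits the trend.
"""

from __future__ import annotations

import warnings

import numpy as np


def cosine_kernel(u, b: float) -> np.ndarray | float:
    """Raised-cosine kernel ``(cos(pi u / b) + 1) / 2`` on ``|u| <= b``.

    ``b`` is the full duration at half maximum: ``K(0) = 1``,
    ``K(+/- b/2) = 1/2`` and the kernel vanishes outside ``[-b, b]``.
    """
    if b <= 0:
        raise ValueError("kernel width b must be positive")
    u_arr = np.asarray(u, dtype=float)
    w = np.where(np.abs(u_arr) <= b, 0.5 * np.cos(np.pi * u_arr / b) + 0.5, 0.0)
    return w if np.ndim(u) else float(w)


def local_slope(
    ages: np.ndarray, values: np.ndarray, T: float, b: float = 10.0
) -> float | np.ndarray:
    """Slope of the kernel-weighted linear fit to (ages, values) at age T.

    This is the smoothed momentaneous effect ``gamma_bar(T)``: the fitted
    slope ``xi_1`` of a weighted linear regression with raised-cosine weights
    ``K(t_i - T)``.  Near the boundary the kernel support is truncated
    (asymmetric); the local-linear form keeps the estimate first-order
    unbiased there.  ``values`` may be 2-D (series in rows), in which case a
    slope per row is returned.
    """
    ages = np.asarray(ages, dtype=float)
    vals = np.asarray(values, dtype=float)
    w = cosine_kernel(ages - T, b)
    if np.count_nonzero(w) < 2:
        raise ValueError(f"fewer than two grid points carry weight around T={T}")
    sw = w.sum()
    tbar = (w * ages).sum() / sw
    dt = ages - tbar
    denom = (w * dt**2).sum()
    if denom <= 0:
        raise ValueError(f"degenerate single-point kernel support at T={T}")
    slope = (vals * (w * dt)).sum(axis=-1) / denom
    return slope


def local_slope_series(
    ages: np.ndarray, values: np.ndarray, eval_ages: np.ndarray, b: float = 10.0
) -> np.ndarray:
    """gamma_bar evaluated on a grid of ages (vectorized over 2-D values)."""
    return np.stack(
        [np.asarray(local_slope(ages, values, float(T), b)) for T in eval_ages],
        axis=-1,
    )


def _second_difference_matrix(n: int) -> np.ndarray:
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D


def hp_filter(series: np.ndarray, lam: float = 50.0) -> np.ndarray:
    """Hodrick-Prescott trend: minimizer of ``|y - tau|^2 + lam |D2 tau|^2``.

    Solved directly as ``(I + lam D'D) tau = y`` (dense symmetric solve; the
    grids here are short).  ``series`` may be 2-D with series in rows.
    ``lam = 0`` returns the input; very large ``lam`` approaches the least
    squares straight line.
    """
    y = np.asarray(series, dtype=float)
    n = y.shape[-1]
    if n < 4:
        raise ValueError("series too short for HP filtering (need >= 4 points)")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    D = _second_difference_matrix(n)
    A = np.eye(n) + lam * (D.T @ D)
    tau = np.linalg.solve(A, np.atleast_2d(y).T).T
    return tau[0] if y.ndim == 1 else tau


def bootstrap_trend_bands(
    ages: np.ndarray,
    Gamma: np.ndarray,
    var_Gamma: np.ndarray,
    trend_fn,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parametric-bootstrap percentile bands for a trend of Gamma_hat.

    Each bootstrap series is ``Gamma_hat(t_k) + eps_k`` with independent
    ``eps_k ~ N(0, var_Gamma[k])`` (uncorrelated errors between time points);
    the trend is refit to every series and the ``alpha/2``/``1 - alpha/2``
    quantiles taken pointwise.  Returns ``(trend, lower, upper)``.

    ``trend_fn`` maps a (batch of) series on ``ages`` to the trend values; it
    must accept a 2-D array of series in rows (both built-in smoothers do).
    """
    if n_boot < 100:
        warnings.warn(
            "n_boot < 100 gives unstable percentile bands", RuntimeWarning, stacklevel=2
        )
    Gamma = np.asarray(Gamma, dtype=float)
    var_Gamma = np.asarray(var_Gamma, dtype=float)
    if np.any(var_Gamma < 0):
        raise ValueError("negative variance")
    rng = np.random.default_rng(seed)
    point = np.asarray(trend_fn(Gamma))
    eps = rng.standard_normal((n_boot, Gamma.size)) * np.sqrt(var_Gamma)
    boot = np.asarray(trend_fn(Gamma + eps))
    lo = np.quantile(boot, alpha / 2.0, axis=0)
    hi = np.quantile(boot, 1.0 - alpha / 2.0, axis=0)
    return point, lo, hi


def basic_bootstrap_ci(
    values: np.ndarray,
    stat_fn,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Basic (resampling-with-replacement) bootstrap CI for a descriptive
    statistic of a sample — utility for stratum summaries."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    point = float(stat_fn(values))
    idx = rng.integers(0, values.size, (n_boot, values.size))
    stats_ = np.array([stat_fn(values[row]) for row in idx])
    lo_q, hi_q = np.quantile(stats_, [alpha / 2.0, 1.0 - alpha / 2.0])
    # basic bootstrap: reflect the percentile interval around the point
    return point, 2 * point - float(hi_q), 2 * point - float(lo_q)
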