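"""Aalen's additive hazards model on the age scale.

The hazard is modeled as ``lambda(t | x) = b0(t) + b1(t) x1 + ... + bp(t) xp``
with every coefficient time-varying.  At each (jittered) event time the
coefficient increment is the least-squares solution regressing the event
indicator on the at-risk design matrix; cumulative coefficients and their
variances accumulate over events (counting-process estimator).  With a single
event per time — guaranteed by the within-year jitter — the increment at an
event with covariate row ``x_e`` and at-risk Gram matrix ``A`` is
``v = A^{-1} x_e`` and the variance contribution is ``diag(v v^T)``.

Yearly instrument-effect levels ``H_hat[k]`` are read off as the difference
of the cumulative coefficient between the last event of year ``k`` and the
last event of year ``k - 1`` (bins ``(k-1, k]``); because the cumulative
coefficient integrates the hazard-level effect over time, this yearly
increment estimates the instrument effect on the hazard *at* age ``k``, and
its variance is the matching difference of cumulative variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def jitter_event_ages(
    event_ages: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Map integer event ages ``a`` to distinct continuous times in ``(a, a+1)``.

    Random noise breaks ties within each year; exact collisions (probability
    zero in floating point, but guarded) are re-drawn.  Seeded and
    reproducible.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ages = np.asarray(event_ages, dtype=float)
    if np.any(ages < 0):
        raise ValueError("event ages must be non-negative")
    times = ages + rng.random(ages.shape)
    # guard against exact collisions
    for _ in range(10):
        order = np.argsort(times)
        dup = np.zeros(times.shape, dtype=bool)
        dup[order[1:]] = times[order[1:]] == times[order[:-1]]
        if not dup.any():
            break
        times[dup] = ages[dup] + rng.random(int(dup.sum()))
    return times


@dataclass
class AalenFit:
    """Cumulative regression coefficients of an additive hazards fit.

    ``event_times`` are strictly increasing jittered times; ``cum_coef`` and
    ``cum_var`` hold, per covariate (columns, intercept first), the step
    values of the cumulative coefficient B_m(t) and its variance right after
    each event.
    """

    event_times: np.ndarray
    cum_coef: np.ndarray  # (n_events, p)
    cum_var: np.ndarray  # (n_events, p)
    covariates: list[str]
    n_events: int
    max_follow_age: float

    def coef_at(self, t: float, covariate: str) -> float:
        """Cumulative coefficient B_m evaluated at time t (step function)."""
        j = self.covariates.index(covariate)
        i = np.searchsorted(self.event_times, t, side="right") - 1
        return 0.0 if i < 0 else float(self.cum_coef[i, j])

    def var_at(self, t: float, covariate: str) -> float:
        j = self.covariates.index(covariate)
        i = np.searchsorted(self.event_times, t, side="right") - 1
        return 0.0 if i < 0 else float(self.cum_var[i, j])


@dataclass
class YearlyIncrements:
    """Yearly instrument-effect levels and variances from an Aalen fit.

    ``H_hat[k-1]`` estimates the hazard-rate difference per unit of the
    covariate at age ``k`` (grid k = 1..K); ``sigma2`` its variance;
    ``events_in_bin`` the number of events in ``(k-1, k]``.
    """

    years: np.ndarray  # 1..K
    H_hat: np.ndarray
    sigma2: np.ndarray
    events_in_bin: np.ndarray
    covariate: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "H_hat": self.H_hat,
                "sigma2": self.sigma2,
                "events": self.events_in_bin,
            }
        )


def fit_aalen(
    cohort: pd.DataFrame,
    covariates: list[str],
    max_follow_age: float = 76.0,
    seed: int = 0,
    entry_col: str | None = None,
) -> AalenFit:
    """Fit Aalen's additive model with all covariate effects time-varying.

    Parameters
    ----------
    cohort
        One row per individual with ``event_age`` (integer years, NaN when
        censored), ``censor_age`` and the covariate columns.
    covariates
        Covariate columns (the instrument among them); an intercept column is
        prepended automatically.
    max_follow_age
        Administrative censoring age; events after it are treated as censored.
    seed
        Seed of the within-year jitter that breaks ties.
    entry_col
        Optional column with delayed-entry (left-truncation) ages; by default
        follow-up runs from birth.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    X = np.column_stack(
        [np.ones(n)] + [cohort[c].to_numpy(dtype=float) for c in covariates]
    )
    p = X.shape[1]

    event_age = cohort["event_age"].to_numpy(dtype=float)
    censor_age = cohort["censor_age"].to_numpy(dtype=float)
    has_event = np.isfinite(event_age)

    rng = np.random.default_rng(seed)
    jittered = np.full(n, np.nan)
    jittered[has_event] = jitter_event_ages(event_age[has_event], rng)
    # events past the administrative cutoff count as censored at the cutoff
    late = has_event & (jittered > max_follow_age)
    is_event = has_event & ~late
    exit_time = np.where(is_event, jittered, np.minimum(censor_age, max_follow_age))
    if not is_event.any():
        raise ValueError("no events before max_follow_age; empty fit")

    order = np.argsort(exit_time, kind="stable")
    X_s = X[order]
    exit_s = exit_time[order]
    ev_s = is_event[order]

    if entry_col is not None:
        entry = cohort[entry_col].to_numpy(dtype=float)[order]
    else:
        entry = None

    # Gram matrix of the at-risk set at each event = suffix sum of x x^T over
    # individuals ordered by exit time (at-risk: exit >= t, left-continuous).
    outer = X_s[:, :, None] * X_s[:, None, :]  # (n, p, p)
    suffix = np.cumsum(outer[::-1], axis=0)[::-1]
    ev_idx = np.flatnonzero(ev_s)
    A = suffix[ev_idx]  # (m, p, p)
    if entry is not None:
        # subtract not-yet-entered individuals per event (small-m path)
        t_ev = exit_s[ev_idx]
        for i, t in enumerate(t_ev):
            notin = entry > t
            if notin.any():
                A[i] -= np.einsum("np,nq->pq", X_s[notin], X_s[notin])
    x_ev = X_s[ev_idx]
    try:
        v = np.linalg.solve(A, x_ev[:, :, None])[:, :, 0]  # (m, p)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "rank-deficient at-risk design at an event time (separation or "
            "too-small risk set)"
        ) from err

    cum_coef = np.cumsum(v, axis=0)
    cum_var = np.cumsum(v**2, axis=0)
    return AalenFit(
        event_times=exit_s[ev_idx],
        cum_coef=cum_coef,
        cum_var=cum_var,
        covariates=["intercept"] + list(covariates),
        n_events=len(ev_idx),
        max_follow_age=float(max_follow_age),
    )


def yearly_increments(fit: AalenFit, covariate: str) -> YearlyIncrements:
    """Yearly levels H_hat(t_k) and variances sigma_k^2 from a fitted model.

    Bin ``k`` covers ``(k-1, k]`` on the jittered time scale; the level is the
    cumulative coefficient at the last event of bin ``k`` minus that at the
    last event of bin ``k-1`` (years with no events contribute 0).
    """
    if covariate not in fit.covariates:
        raise KeyError(f"covariate {covariate!r} not in fit")
    j = fit.covariates.index(covariate)
    K = int(np.ceil(fit.max_follow_age))
    years = np.arange(1, K + 1)
    # last event index in (k-1, k]
    hi = np.searchsorted(fit.event_times, years.astype(float), side="right") - 1
    coef_end = np.where(hi >= 0, fit.cum_coef[np.maximum(hi, 0), j], 0.0)
    var_end = np.where(hi >= 0, fit.cum_var[np.maximum(hi, 0), j], 0.0)
    prev_coef = np.concatenate([[0.0], coef_end[:-1]])
    prev_var = np.concatenate([[0.0], var_end[:-1]])
    counts = np.diff(
        np.searchsorted(fit.event_times, np.arange(0, K + 1, dtype=float), side="right")
    )
    H = np.where(counts > 0, coef_end - prev_coef, 0.0)
    s2 = np.where(counts > 0, var_end - prev_var, 0.0)
    return YearlyIncrements(
        years=years,
        H_hat=H,
        sigma2=s2,
        events_in_bin=counts,
        covariate=covariate,
    )
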