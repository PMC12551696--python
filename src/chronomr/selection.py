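"""Probit-based resampling correction for age-dependent selection into a cohort.

Volunteer cohorts under-sample older individuals with a high exposure, which
shows up as a spurious decline of the mean polygenic score with age at
assessment.  The correction is *relative*: it rectifies the slope of the
mean score over the 40-70 year assessment range, not its absolute level.
Individuals from a young reference set D (below the age cutoff, assumed
least affected by selection) are re-sampled with probit probabilities
``p_i = Phi(d_i - mu_k)`` (``d_i`` the standardized exposure) and appended
to age stratum ``k``, with ``mu_k`` chosen by grid search so that the
corrected stratum mean score matches the original mean plus the expected
offset ``m_k`` within a tolerance ``eps``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SelectionPlan:
    """Bookkeeping of a selection-correction run."""

    reference_ids: np.ndarray
    strata: np.ndarray
    offsets: np.ndarray  # m_k per stratum
    mu_by_stratum: np.ndarray
    appended_counts: np.ndarray
    residuals: np.ndarray  # achieved |mean - target| per stratum
    tolerance: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum_age": self.strata,
                "offset_m": self.offsets,
                "mu": self.mu_by_stratum,
                "appended": self.appended_counts,
                "residual": self.residuals,
            }
        )


def expected_offsets(
    cohort: pd.DataFrame,
    score_col: str = "pgs",
    age_col: str = "age_at_assessment",
    age_range: tuple[int, int] = (40, 70),
    min_stratum_size: int = 30,
) -> pd.DataFrame:
    """Expected mean-score offsets ``m_k`` per age stratum.

    Fits a straight line to the stratum mean scores over the assessment age
    range and anchors at age 40: ``m_k = fitted(40) - fitted(k)`` — the
    amount the mean score at stratum ``k`` falls short of the age-40 level.
    """
    lo, hi = age_range
    ages = cohort[age_col].to_numpy()
    mask = (ages >= lo) & (ages <= hi)
    sub = cohort.loc[mask]
    means = sub.groupby(age_col)[score_col].agg(["mean", "size"])
    means = means[means["size"] >= min_stratum_size]
    if len(means) < 2:
        raise ValueError("need at least 2 age strata with enough individuals")
    slope, intercept = np.polyfit(
        means.index.to_numpy(dtype=float), means["mean"].to_numpy(), 1
    )
    k = means.index.to_numpy(dtype=float)
    fitted = intercept + slope * k
    fitted40 = intercept + slope * lo
    return pd.DataFrame({"stratum_age": k.astype(int), "m_k": fitted40 - fitted})


def rectify_sample(
    cohort: pd.DataFrame,
    score_col: str = "pgs",
    exposure_col: str = "exposure_z",
    age_col: str = "age_at_assessment",
    reference_age_cutoff: int = 45,
    age_range: tuple[int, int] = (40, 70),
    tolerance: float = 0.005,
    mu_grid: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SelectionPlan]:
    """Append probit-resampled reference individuals until stratum mean scores
    are rectified.

    For each age stratum ``k`` in the assessment range, reference individuals
    (assessment age below ``reference_age_cutoff``) are selected with
    probability ``Phi(d_i - mu_k)`` and appended with assigned assessment age
    ``k``; ``mu_k`` comes from a table search over ``mu_grid`` minimizing the
    deviation of the corrected stratum mean from ``original mean + m_k``.
    Appended rows keep all original data apart from the assigned age and get
    ``duplicate_flag = True``.

    Returns the expanded cohort and the SelectionPlan; strata whose best
    residual exceeds ``tolerance`` are reported in the plan (best-achieved
    residual kept).
    """
    if mu_grid is None:
        # wide enough that the upper end selects single extreme individuals;
        # +inf encodes the no-append option for already-rectified strata
        mu_grid = np.concatenate([np.arange(-4.0, 8.0 + 1e-9, 0.01), [np.inf]])
    offsets = expected_offsets(cohort, score_col, age_col, age_range)
    ref = cohort[cohort[age_col] < reference_age_cutoff]
    if len(ref) == 0:
        raise ValueError("empty reference set below the age cutoff")
    d = ref[exposure_col].to_numpy(dtype=float)
    scores_ref = ref[score_col].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    appended_parts: list[pd.DataFrame] = []
    mus, counts, residuals = [], [], []
    for row in offsets.itertuples(index=False):
        k, m_k = int(row.stratum_age), float(row.m_k)
        in_k = cohort[age_col].to_numpy() == k
        n_k = int(in_k.sum())
        mean_k = float(cohort.loc[in_k, score_col].mean())
        target = mean_k + m_k
        # One uniform draw per reference individual: i is selected at mu iff
        # u_i < Phi(d_i - mu), i.e. iff mu < d_i - Phi^{-1}(u_i).  Selection is
        # therefore nested/monotone along the mu grid, and the whole table
        # search reduces to a sort plus suffix sums.
        u = rng.random(len(ref))
        mu_star = d - stats.norm.ppf(u)
        order = np.argsort(mu_star)
        ms, ss = mu_star[order], scores_ref[order]
        suffix = np.concatenate([np.cumsum(ss[::-1])[::-1], [0.0]])
        pos = np.searchsorted(ms, mu_grid, side="right")
        n_sel = len(ref) - pos
        corr_mean = (n_k * mean_k + suffix[pos]) / (n_k + n_sel)
        resid_grid = np.abs(corr_mean - target)
        # prefer the largest mu (fewest appended individuals) that already
        # meets the acceptance rule; otherwise fall back to the best residual
        ok = np.flatnonzero(resid_grid <= tolerance)
        j = int(ok[-1]) if ok.size else int(np.argmin(resid_grid))
        resid, mu_k = float(resid_grid[j]), float(mu_grid[j])
        sel = mu_star > mu_k
        part = ref.loc[sel].copy()
        part[age_col] = k
        part["duplicate_flag"] = True
        appended_parts.append(part)
        mus.append(mu_k)
        counts.append(int(sel.sum()))
        residuals.append(resid)

    base = cohort.copy()
    base["duplicate_flag"] = False
    expanded = pd.concat([base] + appended_parts, ignore_index=True)
    plan = SelectionPlan(
        reference_ids=ref["id"].to_numpy(),
        strata=offsets["stratum_age"].to_numpy(),
        offsets=offsets["m_k"].to_numpy(),
        mu_by_stratum=np.array(mus),
        appended_counts=np.array(counts),
        residuals=np.array(residuals),
        tolerance=tolerance,
        seed=seed,
    )
    return expanded, plan
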