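"""Exposure standardization, polygenic-score construction and Steiger filtering.

The exposure is z-transformed within sex x age strata (the lowest stratum
pools everyone aged 40 or below, the highest everyone 70 or above) so that
the instrument effect is expressed in within-stratum SD units at every age.
Polygenic scores are built by cross-fitting: each half of the cohort is
scored with weights estimated in the other half, standardized within half,
then remerged — no individual is ever scored with weights from its own split.

Steiger directionality filtering compares, per SNP, the correlation with the
exposure against the correlation with the outcome using the test for two
dependent overlapping correlations sharing one variable: Fisher-z transform
both, then

    z = (Z_gx - Z_gy) * sqrt((N - 3) / (2 h (1 - rho_xy))),
    h = (1 - f rho2bar) / (1 - rho2bar),
    f = (1 - rho_xy) / (2 (1 - rho2bar)),
    rho2bar = (rho_gx^2 + rho_gy^2) / 2,

one-tailed against H1: rho_gx > rho_gy, with Benjamini-Hochberg control of
the FDR across SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

AGE_POOL_LOW = 40
AGE_POOL_HIGH = 70


def pooled_age_stratum(ages: np.ndarray) -> np.ndarray:
    """Integer age strata with the <=40 and >=70 tails pooled."""
    a = np.asarray(ages)
    return np.clip(a.astype(int), AGE_POOL_LOW, AGE_POOL_HIGH)


def ztransform_by_stratum(
    cohort: pd.DataFrame,
    exposure: str = "exposure_raw",
    out: str = "exposure_z",
    sex_col: str | None = "sex",
    age_col: str = "age_at_assessment",
) -> pd.DataFrame:
    """z-transform the exposure within each (sex, pooled-age) stratum.

    Uses the n-1 SD convention.  Returns a copy with the ``out`` column
    filled; every stratum ends up with mean 0 and SD 1.
    """
    df = cohort.copy()
    strata = [pooled_age_stratum(df[age_col].to_numpy())]
    if sex_col is not None and sex_col in df.columns:
        strata.append(df[sex_col].to_numpy())
    key = pd.MultiIndex.from_arrays(strata)
    grouped = df[exposure].groupby(key)
    sizes = grouped.transform("size")
    if (sizes < 2).any():
        raise ValueError("stratum with fewer than 2 individuals cannot be standardized")
    mean = grouped.transform("mean")
    sd = grouped.transform("std")  # ddof=1
    df[out] = ((df[exposure] - mean) / sd).to_numpy()
    return df


@dataclass
class PGSWeights:
    """SNP weights (exposure-SD per effect allele) from one discovery split."""

    table: pd.DataFrame  # columns: snp_id, effect_allele, weight, source_split

    def __post_init__(self) -> None:
        req = {"snp_id", "effect_allele", "weight", "source_split"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"weights table missing columns {sorted(missing)}")
        if not np.all(np.isfinite(self.table["weight"])):
            raise ValueError("non-finite weights")
        for split, sub in self.table.groupby("source_split"):
            if sub["snp_id"].duplicated().any():
                raise ValueError(f"duplicate snp_id within split {split}")

    def for_split(self, split: str) -> pd.DataFrame:
        return self.table[self.table["source_split"] == split]


def compute_pgs(genotypes: pd.DataFrame, weights: pd.DataFrame) -> np.ndarray:
    """Weighted allele-dosage score ``sum_j w_j g_ij``.

    ``genotypes`` is a wide table with one dosage column per SNP in [0, 2];
    missing dosages are mean-imputed as twice the allele frequency observed
    in the scoring sample.
    """
    score = np.zeros(len(genotypes))
    for _, row in weights.iterrows():
        snp = row["snp_id"]
        if snp not in genotypes.columns:
            raise KeyError(f"SNP {snp!r} absent from genotype table")
        g = genotypes[snp].to_numpy(dtype=float)
        finite = np.isfinite(g)
        if not finite.all():
            af = np.nanmean(g) / 2.0
            g = np.where(finite, g, 2.0 * af)
        if np.nanmin(g) < 0 or np.nanmax(g) > 2:
            raise ValueError(f"dosages for {snp!r} outside [0, 2]")
        score += row["weight"] * g
    return score


def crossfit_pgs(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    weights: PGSWeights,
    out: str = "pgs",
) -> pd.DataFrame:
    """Cross-fitted polygenic scores: A scored with B-derived weights and vice
    versa, standardized (n-1 SD) within each split, then remerged.

    Adds ``out`` (the standardized score) and ``pgs_weights_from`` (provenance
    of the weights each individual was scored with).
    """
    ids_a = set(cohort_a["id"])
    ids_b = set(cohort_b["id"])
    if ids_a & ids_b:
        raise ValueError("cohort splits share individual ids")
    parts = []
    for sub, own, other in ((cohort_a, "A", "B"), (cohort_b, "B", "A")):
        w = weights.for_split(other)
        raw = compute_pgs(sub, w)
        std = (raw - raw.mean()) / raw.std(ddof=1)
        part = sub.copy()
        part[out] = std
        part["pgs_weights_from"] = other
        part["split"] = own
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def steiger_test(
    rho_gx: float, rho_gy: float, n: int, rho_xy: float
) -> tuple[float, float]:
    """Steiger z and one-sided p for H1: rho_gx > rho_gy (shared variable g).

    Fisher-transforms both correlations and scales their difference by the
    dependent-overlapping-correlations factor; the p-value is the upper tail
    of the standard normal.
    """
    for r in (rho_gx, rho_gy, rho_xy):
        if abs(r) >= 1:
            raise ValueError("|rho| must be < 1 (Fisher transform undefined)")
    if n <= 3:
        raise ValueError("need n > 3")
    z_gx = np.arctanh(rho_gx)
    z_gy = np.arctanh(rho_gy)
    rho2bar = (rho_gx**2 + rho_gy**2) / 2.0
    f = 0.5 * (1.0 - rho_xy) / (1.0 - rho2bar)
    h = (1.0 - f * rho2bar) / (1.0 - rho2bar)
    scale = 2.0 * h * (1.0 - rho_xy)
    if scale <= 0:
        # f*rho2bar > 1: the variance factor degenerates (extreme
        # correlation configurations outside the statistic's domain)
        raise ValueError("correlation configuration outside the test's domain")
    z = (z_gx - z_gy) * np.sqrt((n - 3.0) / scale)
    p = float(stats.norm.sf(z))
    return float(z), p


def estimate_rho_xy(rho_gx: np.ndarray, rho_gy: np.ndarray) -> float:
    """Exposure-outcome correlation implied by the SNP effects: the median of
    rho_gy / rho_gx over SNPs (assuming X -> Y)."""
    rho_gx = np.asarray(rho_gx, dtype=float)
    rho_gy = np.asarray(rho_gy, dtype=float)
    return float(np.median(rho_gy / rho_gx))


def steiger_filter(
    snps: pd.DataFrame,
    n: int,
    fdr: float = 0.05,
    rho_xy: float | None = None,
) -> pd.DataFrame:
    """Per-SNP Steiger tests with Benjamini-Hochberg FDR control.

    ``snps`` needs columns ``snp_id``, ``rho_gx``, ``rho_gy``.  When
    ``rho_xy`` is not given it is estimated as the median of
    ``rho_gy / rho_gx``.  Returns the table with ``z_stat``, ``p_one_sided``,
    ``q_fdr`` and ``keep`` (q <= fdr) appended.
    """
    if len(snps) == 0:
        raise ValueError("need at least one SNP")
    out = snps.copy()
    if rho_xy is None:
        rho_xy = estimate_rho_xy(out["rho_gx"].to_numpy(), out["rho_gy"].to_numpy())
    zp = [
        steiger_test(r.rho_gx, r.rho_gy, n, rho_xy)
        for r in out.itertuples(index=False)
    ]
    out["z_stat"] = [z for z, _ in zp]
    out["p_one_sided"] = [p for _, p in zp]
    _, q, _, _ = multipletests(out["p_one_sided"], method="fdr_bh")
    out["q_fdr"] = q
    out["keep"] = out["q_fdr"] <= fdr
    out.attrs["rho_xy"] = rho_xy
    return out


def point_biserial_outcome_correlations(
    cohort: pd.DataFrame,
    snp_cols: list[str],
    exposure: str = "exposure_z",
    event_cutoff_age: float = 76.0,
) -> pd.DataFrame:
    """Per-SNP correlations with the exposure and with the event-by-cutoff
    indicator (point-biserial convention for the binary outcome)."""
    y = (cohort["event_age"] <= event_cutoff_age).fillna(False).astype(float)
    x = cohort[exposure].to_numpy(dtype=float)
    rows = []
    for snp in snp_cols:
        g = cohort[snp].to_numpy(dtype=float)
        rows.append(
            {
                "snp_id": snp,
                "rho_gx": float(np.corrcoef(g, x)[0, 1]),
                "rho_gy": float(np.corrcoef(g, y)[0, 1]),
            }
        )
    return pd.DataFrame(rows)
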