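"""Tab-delimited cohort and weights tables (UTF-8, '.' decimal)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .prep import PGSWeights

log = logging.getLogger("chronomr")

REQUIRED_COHORT_COLUMNS = (
    "id",
    "exposure_raw",
    "age_at_assessment",
    "event_age",
    "censor_age",
)


class SchemaError(ValueError):
    """A required column is missing or a value range is violated."""


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-delimited cohort table."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing required column(s): {missing}")
    for col in ("exposure_raw", "age_at_assessment", "event_age", "censor_age"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df["age_at_assessment"].isna().any() or df["censor_age"].isna().any():
        raise SchemaError("unparseable ages in cohort table")
    bad = df["event_age"].notna() & (df["event_age"] > df["censor_age"])
    if bad.any():
        raise SchemaError(
            f"{int(bad.sum())} row(s) with event_age > censor_age"
        )
    log.info(
        "read cohort: %d rows, %d with events, %.1f%% exposure missing",
        len(df),
        int(df["event_age"].notna().sum()),
        100.0 * df["exposure_raw"].isna().mean(),
    )
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_weights(path: str | Path) -> PGSWeights:
    """Read a tab-delimited (snp_id, effect_allele, weight, source_split) table."""
    return PGSWeights(pd.read_csv(path, sep="\t"))


def write_weights(weights: PGSWeights, path: str | Path) -> None:
    weights.table.to_csv(path, sep="\t", index=False)
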