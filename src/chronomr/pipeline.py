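"""End-to-end time-resolved MR pipeline.

Stages: exposure preparation -> age-varying instrument fit -> additive-hazards
fit -> yearly increments -> time-resolved Wald ratios (momentaneous +
cumulative effects) -> smoothed trends with parametric-bootstrap bands.
Each stage is a thin call into the corresponding module; results are returned
as a bundle of tidy frames plus a provenance record (settings, seeds,
config hash) and can be written to disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aalen import fit_aalen, yearly_increments
from .config import RunConfig
from .estimator import effect_series, naive_wald_constant, naive_wald_timevarying
from .instrument import (
    InstrumentEffectFunction,
    fit_beta_constant,
    fit_beta_linear,
    fit_beta_quartic,
)
from .prep import ztransform_by_stratum
from .selection import rectify_sample
from .trend import bootstrap_trend_bands, hp_filter, local_slope_series

log = logging.getLogger("chronomr")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage
        self.cause = err


@dataclass
class PipelineResult:
    effects: pd.DataFrame  # per-year tidy effect table
    trends: pd.DataFrame  # per-year trend table with bootstrap bands
    beta_fit: InstrumentEffectFunction
    beta_const: float
    provenance: dict
    sex_results: dict | None = None  # per-sex PipelineResult when stratified

    def write(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in (("effects", self.effects), ("trends", self.trends)):
            df.assign(config_hash=self.provenance["config_hash"]).to_csv(
                out / f"{name}.tsv", sep="\t", index=False
            )
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))
        (out / "instrument_fit.json").write_text(
            json.dumps(
                {
                    "model_kind": self.beta_fit.model_kind,
                    "coefficients": self.beta_fit.coefficients.tolist(),
                    "covariance": self.beta_fit.covariance.tolist(),
                    "n": self.beta_fit.n,
                    "age_domain": list(self.beta_fit.age_domain),
                    "beta_const": self.beta_const,
                },
                indent=2,
            )
        )


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as err:  # noqa: BLE001 - annotate with stage name
        raise PipelineError(name, err) from err


def run_pipeline(cohort: pd.DataFrame, config: RunConfig) -> PipelineResult:
    """Run the full analysis on a prepared cohort table.

    With ``sex_stratified`` the pipeline additionally reruns itself on each
    sex subset (independent instrument refits per sex); the per-sex results
    are attached to ``sex_results``.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    exposure = config.exposure_col

    if config.selection_correct:
        cohort, _plan = _stage(
            "selection-correct",
            rectify_sample,
            cohort,
            score_col=config.instrument_col,
            exposure_col=exposure,
            seed=int(seeds[3]),
        )

    if config.standardize:
        cohort = _stage(
            "standardize", ztransform_by_stratum, cohort, exposure=exposure
        )
        exposure = "exposure_z"

    fit_fn = fit_beta_quartic if config.beta_model == "quartic" else fit_beta_linear
    beta = _stage(
        "fit-instrument",
        fit_fn,
        cohort,
        instrument=config.instrument_col,
        covariates=config.covariate_cols,
        exposure=exposure,
    )
    beta_const_fit = _stage(
        "fit-instrument",
        fit_beta_constant,
        cohort,
        instrument=config.instrument_col,
        covariates=config.covariate_cols,
        exposure=exposure,
    )
    beta_const = float(beta_const_fit.coefficients[0])

    afit = _stage(
        "aalen",
        fit_aalen,
        cohort,
        covariates=[config.instrument_col] + list(config.covariate_cols),
        max_follow_age=config.max_follow_age,
        seed=int(seeds[0]),
    )
    incr = _stage("aalen", yearly_increments, afit, config.instrument_col)

    series = _stage(
        "trmr",
        effect_series,
        incr,
        beta,
        floor=config.weak_instrument_floor,
        alpha=config.alpha,
    )
    eff = series.to_frame()
    eff["naive_const"] = naive_wald_constant(incr, beta_const)
    eff["naive_timevarying"] = naive_wald_timevarying(
        incr, beta, floor=config.weak_instrument_floor
    )
    eff["events"] = incr.events_in_bin

    ages = series.years.astype(float)
    hp_point, hp_lo, hp_hi = _stage(
        "trend",
        bootstrap_trend_bands,
        ages,
        series.Gamma_mid,
        series.var_Gamma_mid,
        lambda y: hp_filter(y, config.hp_lambda),
        n_boot=config.n_boot,
        alpha=config.alpha,
        seed=int(seeds[1]),
    )
    gb_point, gb_lo, gb_hi = _stage(
        "trend",
        bootstrap_trend_bands,
        ages,
        series.Gamma_mid,
        series.var_Gamma_mid,
        lambda y: local_slope_series(ages, y, ages, config.fdhm_b),
        n_boot=config.n_boot,
        alpha=config.alpha,
        seed=int(seeds[2]),
    )
    trends = pd.DataFrame(
        {
            "age": ages,
            "Gamma_trend": hp_point,
            "Gamma_trend_lo": hp_lo,
            "Gamma_trend_hi": hp_hi,
            "gamma_bar": gb_point,
            "gamma_bar_lo": gb_lo,
            "gamma_bar_hi": gb_hi,
        }
    )

    provenance = {
        "chronomr_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": [int(s) for s in seeds],
        "n_individuals": int(len(cohort)),
        "n_events_fit": int(afit.n_events),
    }
    sex_results = None
    if config.sex_stratified:
        if "sex" not in cohort.columns:
            raise PipelineError("sex-stratify", KeyError("no 'sex' column"))
        import dataclasses

        sub_cfg = dataclasses.replace(config, sex_stratified=False)
        sex_results = {
            int(s): run_pipeline(sub.reset_index(drop=True), sub_cfg)
            for s, sub in cohort.groupby("sex")
        }

    return PipelineResult(
        effects=eff,
        trends=trends,
        beta_fit=beta,
        beta_const=beta_const,
        provenance=provenance,
        sex_results=sex_results,
    )
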