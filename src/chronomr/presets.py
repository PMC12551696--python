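"""Validation-scenario presets.

``validation`` is the main validation scenario: quartic instrument effect
``beta_G(t) = 0.3 - 9e-4 t - 4e-9 t^4``, momentaneous exposure effect
``gamma(t) = c_g t^4`` (life-course effect proportional to ``T^5``) and an
outcome prevalence of 15% by age 80 after baseline calibration.  The
``s4_low`` / ``s4_high`` variants re-target prevalence to 3% and 30%,
scaling the exposure-effect magnitude by the same ratio so the
effect-to-baseline-hazard balance of the main scenario is preserved.
``s5`` drives the exposure with three SNPs of deliberately diverse
age-dependent effects and uses their unweighted dosage sum as the polygenic
instrument.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .simulate import SimulationConfig

#: calibrated baseline for the validation scenario at 15% prevalence (seed-stable
#: starting point; calibrate_baseline refines it)
VALIDATION_BASELINE = 1.07e-3

PRESET_NAMES = ("validation", "low-prevalence", "high-prevalence", "multisnp")


def validation_config(n: int = 100_000, seed: int = 0) -> SimulationConfig:
    """Main validation scenario (15% prevalence by age 80)."""
    return SimulationConfig(n_individuals=n, seed=seed, baseline_hazard=VALIDATION_BASELINE)


def _scale_outcome_side(base: SimulationConfig, factor: float) -> SimulationConfig:
    """Scale every term of the latent hazard gradient by a common factor.

    Rescaling gamma, baseline, offset and the outcome-side confounder and
    covariate profiles together changes disease frequency while preserving
    the hazard-positivity structure of the main scenario.
    """
    au, az = base.confounder_outcome_profile, base.covariate_outcome_profile
    return replace(
        base,
        gamma_scale=base.gamma_scale * factor,
        baseline_hazard=base.baseline_hazard * factor,
        hazard_offset=base.hazard_offset * factor,
        confounder_outcome_profile=lambda t: factor * np.asarray(au(t), dtype=float),
        covariate_outcome_profile=lambda t: factor * np.asarray(az(t), dtype=float),
    )


def low_prevalence_config(n: int = 100_000, seed: int = 0) -> SimulationConfig:
    """Low-prevalence robustness variant (3% by age 80)."""
    return _scale_outcome_side(validation_config(n, seed), 0.2)


def high_prevalence_config(n: int = 100_000, seed: int = 0) -> SimulationConfig:
    """High-prevalence robustness variant (30% by age 80)."""
    return _scale_outcome_side(validation_config(n, seed), 2.4)


def diverse_snp_profiles() -> list[tuple[float, callable]]:
    """Three SNPs with diverse age-dependent effects on the exposure:
    strongly decreasing, increasing, and quartically decaying."""
    return [
        (0.3, lambda t: 0.35 - 3.0e-3 * np.asarray(t, dtype=float)),
        (0.5, lambda t: 0.08 + 2.0e-3 * np.asarray(t, dtype=float)),
        (0.2, lambda t: 0.30 - 8.0e-9 * np.asarray(t, dtype=float) ** 4),
    ]


def preset_config(name: str, n: int = 100_000, seed: int = 0) -> SimulationConfig:
    if name == "validation":
        return validation_config(n, seed)
    if name == "low-prevalence":
        return low_prevalence_config(n, seed)
    if name == "high-prevalence":
        return high_prevalence_config(n, seed)
    if name == "multisnp":
        return validation_config(n, seed)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def preset_target_prevalence(name: str) -> float:
    return {"validation": 0.15, "low-prevalence": 0.03, "high-prevalence": 0.30, "multisnp": 0.15}[name]
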