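"""Run configuration for the end-to-end analysis pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Analysis settings; defaults reproduce the reference protocol
    (administrative cutoff 76 y, yearly grid, FDHM 10 y, HP penalty 50,
    10,000 bootstrap samples, alpha 0.05)."""

    cohort_path: str = ""
    weights_path: str | None = None
    output_dir: str = "chronomr_results"

    exposure_col: str = "exposure_raw"
    instrument_col: str = "instrument"
    covariate_cols: list[str] = field(default_factory=list)
    standardize: bool = True
    sex_stratified: bool = False
    selection_correct: bool = False

    max_follow_age: float = 76.0
    beta_model: str = "quartic"  # "quartic" | "linear"
    weak_instrument_floor: float = 0.01
    fdhm_b: float = 10.0
    hp_lambda: float = 50.0
    n_boot: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_model not in ("quartic", "linear"):
            raise ValueError("beta_model must be 'quartic' or 'linear'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_follow_age <= 0:
            raise ValueError("max_follow_age must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
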