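"""Cohort / ground-truth / configuration readers and writers.

All tables are plain delimited text with documented headers; ground truth
and resolved configurations are JSON/YAML sidecars.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import COHORT_COLUMNS, CohortValidationError, validate_cohort
from .synthetic import GroundTruth


def read_cohort(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a tidy cohort CSV/TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    try:
        return validate_cohort(df)
    except CohortValidationError as exc:
        raise CohortValidationError(f"{path}: {exc}") from exc


def write_cohort(cohort: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    cohort.loc[:, COHORT_COLUMNS].to_csv(path, sep=sep, index=False)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "planted_factor_order": truth.planted_factor_order,
        "converter_ids": list(truth.converter_ids),
        "outlier_records": [list(r) for r in truth.outlier_records],
        "beta_true": {k: list(map(float, v)) for k, v in truth.beta_true.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        planted_factor_order=payload["planted_factor_order"],
        converter_ids=payload["converter_ids"],
        outlier_records=[tuple(r) for r in payload["outlier_records"]],
        beta_true={k: np.asarray(v) for k, v in payload["beta_true"].items()},
    )


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    """Fully resolved parameters of one reproducible pipeline run."""

    cohort_path: str | None = None
    results_dir: str = "results"
    # synthetic generation (used when no cohort_path is given)
    simulate: dict = field(default_factory=dict)
    # quality control
    qc_percentile: float = 10.0
    qc_alpha: float = 0.05
    qc_scope: str = "per-modality"
    # model fitting
    variants: tuple[str, ...] = (
        "fixed_robust",
        "mixed_intercept",
        "mixed_intercept_slope",
    )
    # trajectories
    shape: str = "linear"
    sigmoid_midpoint: float | None = None
    sigmoid_steepness: float | None = None
    weighting: str = "uniform"
    # bootstrap
    bootstrap_B: int = 500
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if not 0 < self.qc_percentile < 100:
            raise ConfigError("qc_percentile must lie in (0, 100)")
        if not 0 < self.qc_alpha < 1:
            raise ConfigError("qc_alpha must lie in (0, 1)")
        if self.qc_scope not in ("per-biomarker", "per-modality"):
            raise ConfigError("qc_scope must be 'per-biomarker' or 'per-modality'")
        bad = set(self.variants) - {
            "fixed_robust",
            "mixed_intercept",
            "mixed_intercept_slope",
        }
        if bad or not self.variants:
            raise ConfigError(f"invalid model variants: {sorted(bad) or 'empty'}")
        if self.shape not in ("linear", "sigmoid"):
            raise ConfigError("shape must be 'linear' or 'sigmoid'")
        if self.weighting not in ("uniform", "empirical"):
            raise ConfigError("weighting must be 'uniform' or 'empirical'")
        if self.bootstrap_B < 2:
            raise ConfigError("bootstrap_B must be >= 2")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "variants" in raw:
            raw["variants"] = tuple(raw["variants"])
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["variants"] = list(self.variants)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
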