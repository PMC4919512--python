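"""Synthetic longitudinal multimodal cohorts with known ground truth.

The generator emulates the statistical structure assumed by the per-biomarker
progression model: each observation is a linear fixed-effects predictor in
age, disease state (DS), sex, education and apoe-e4 allele count (all 10
pairwise interactions included), plus a subject-level random intercept, a
subject-level random age slope, and Gaussian noise.

The temporal ordering of the five biological factors is *planted* through
factor-specific DS coefficient magnitudes: under the linear model the
abnormality of a biomarker relative to healthy aging is monotone in its
|DS effect|, so the generator's ``planted_factor_order`` is the order any
correct end-to-end analysis must recover.

All randomness flows from a single root seed through independent named
streams (cohort, converters, outliers), so planting operations never perturb
the cohort draws themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import imaging_biomarker_id, validate_cohort
from .design import DESIGN_COLUMNS, design_matrix

DEFAULT_FACTORS = ("vascular", "amyloid", "metabolic", "functional", "structural")
DEFAULT_SCALARS = ("mmse", "csf_abeta42", "csf_tau", "csf_ptau")

_STREAMS = {"cohort": 0, "converters": 1, "outliers": 2}


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible generator for a named sub-stream of ``seed``."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``beta_true`` maps biomarker id to a length-16 coefficient vector aligned
    with :data:`mfdpm.design.DESIGN_COLUMNS`; when ``None`` a default table is
    built from ``factor_ds_effects`` / ``scalar_ds_effects`` (DS main effects
    that plant the factor ordering) plus small common covariate effects.
    """

    n_subjects: int = 200
    n_visits: int = 4
    n_regions: int = 78
    factor_names: tuple[str, ...] = DEFAULT_FACTORS
    scalar_biomarker_names: tuple[str, ...] = DEFAULT_SCALARS
    age_range: tuple[float, float] = (40.0, 70.0)
    group_proportions: tuple[float, ...] = (0.35, 0.25, 0.20, 0.20)
    factor_ds_effects: dict[str, float] | None = None
    scalar_ds_effects: dict[str, float] | None = None
    beta_true: dict[str, np.ndarray] | None = None
    random_effect_sd: tuple[float, float] = (0.3, 0.01)
    noise_sd: float = 1.0
    converter_fraction: float = 0.0
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be a positive integer")
        if self.n_visits < 1:
            raise ValueError("n_visits must be a positive integer")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if abs(sum(self.group_proportions) - 1.0) > 1e-12:
            raise ValueError("group_proportions must sum to 1 (simplex)")
        if any(p < 0 for p in self.group_proportions):
            raise ValueError("group_proportions must be non-negative")
        if any(s < 0 for s in self.random_effect_sd):
            raise ValueError("random_effect_sd entries must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.converter_fraction < 1:
            raise ValueError("converter_fraction must lie in [0, 1)")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must lie in [0, 1)")
        if self.outlier_magnitude <= 0:
            raise ValueError("outlier_magnitude must be > 0")


@dataclass
class GroundTruth:
    """What was planted: the factor ordering, converters, outliers, betas."""

    planted_factor_order: list[str]
    converter_ids: list[str] = field(default_factory=list)
    outlier_records: list[tuple[str, int, str]] = field(default_factory=list)
    beta_true: dict[str, np.ndarray] = field(default_factory=dict)


def default_ds_effects(factor_names, gap: float = 0.25, base: float = 0.5):
    """Descending |DS| effects down ``factor_names``, adjacent gaps ``gap``."""
    n = len(factor_names)
    return {f: base + gap * (n - 1 - i) for i, f in enumerate(factor_names)}


_DEFAULT_SCALAR_DS = {"mmse": 1.2, "csf_abeta42": 0.9, "csf_tau": 0.7, "csf_ptau": 0.6}


def build_beta_table(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Per-biomarker 16-coefficient vectors realizing the planted ordering."""
    if config.beta_true is not None:
        return {k: np.asarray(v, dtype=float) for k, v in config.beta_true.items()}
    ds_eff = config.factor_ds_effects or default_ds_effects(config.factor_names)
    scalar_eff = config.scalar_ds_effects or {
        s: _DEFAULT_SCALAR_DS.get(s, 0.8) for s in config.scalar_biomarker_names
    }
    idx = {name: i for i, name in enumerate(DESIGN_COLUMNS)}
    base = np.zeros(len(DESIGN_COLUMNS))
    base[idx["age"]] = 0.02
    base[idx["sex"]] = 0.10
    base[idx["education"]] = 0.01
    base[idx["apoe4"]] = 0.20
    table: dict[str, np.ndarray] = {}
    for factor in config.factor_names:
        for region in range(config.n_regions):
            beta = base.copy()
            beta[idx["ds"]] = ds_eff[factor]
            table[imaging_biomarker_id(factor, region)] = beta
    for name in config.scalar_biomarker_names:
        beta = base.copy()
        beta[idx["ds"]] = scalar_eff[name]
        table[name] = beta
    return table


def _planted_order(config: SyntheticConfig, betas: dict[str, np.ndarray]) -> list[str]:
    ds_col = DESIGN_COLUMNS.index("ds")
    mags = {}
    for factor in config.factor_names:
        vals = [
            abs(betas[imaging_biomarker_id(factor, r)][ds_col])
            for r in range(config.n_regions)
        ]
        mags[factor] = float(np.mean(vals))
    return sorted(config.factor_names, key=lambda f: (-mags[f], f))


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a longitudinal cohort under the linear mixed generative model.

    Returns the tidy long-format cohort table and a :class:`GroundTruth`
    recording the planted factor ordering and true coefficients.  With the
    same config (including seed) the output is bit-identical across calls.
    If ``converter_fraction`` / ``outlier_fraction`` are positive, the
    corresponding planting operations are applied after the clean draw.
    """
    rng = _stream(config.seed, "cohort")
    n_sub, n_vis = config.n_subjects, config.n_visits
    subjects = [f"S{i:05d}" for i in range(n_sub)]

    base_age = rng.uniform(*config.age_range, size=n_sub)
    sex = rng.integers(0, 2, size=n_sub)
    education = rng.integers(6, 21, size=n_sub)
    apoe4 = rng.choice([0, 1, 2], size=n_sub, p=[0.6, 0.3, 0.1])
    ds = rng.choice([1, 2, 3, 4], size=n_sub, p=list(config.group_proportions))

    sub_idx = np.repeat(np.arange(n_sub), n_vis)
    visit = np.tile(np.arange(n_vis), n_sub)
    age = base_age[sub_idx] + visit  # yearly visits

    cov = pd.DataFrame(
        {
            "subject_id": np.repeat(subjects, n_vis),
            "visit": visit,
            "age": age,
            "sex": sex[sub_idx],
            "education": education[sub_idx].astype(float),
            "apoe4": apoe4[sub_idx],
            "ds": ds[sub_idx],
        }
    )
    X = design_matrix(cov)

    betas = build_beta_table(config)
    biomarkers = list(betas)
    B = np.column_stack([betas[b] for b in biomarkers])  # (16, M)
    linpred = X @ B  # (N, M)

    sd_b0, sd_slope = config.random_effect_sd
    b0 = rng.normal(0.0, 1.0, size=(n_sub, len(biomarkers))) * sd_b0
    slope = rng.normal(0.0, 1.0, size=(n_sub, len(biomarkers))) * sd_slope
    noise = rng.normal(0.0, 1.0, size=linpred.shape) * config.noise_sd
    values = linpred + b0[sub_idx] + slope[sub_idx] * age[:, None] + noise

    long = pd.concat(
        [
            cov.assign(biomarker_id=bm, value=values[:, j])
            for j, bm in enumerate(biomarkers)
        ],
        ignore_index=True,
    )
    cohort = validate_cohort(long)
    truth = GroundTruth(
        planted_factor_order=_planted_order(config, betas), beta_true=betas
    )
    if config.converter_fraction > 0:
        cohort, truth = plant_converters(
            cohort, truth, config.converter_fraction, config.seed
        )
    if config.outlier_fraction > 0:
        cohort, truth = plant_outliers(
            cohort, truth, config.outlier_fraction, config.outlier_magnitude,
            config.seed,
        )
    return cohort, truth


def plant_converters(
    cohort: pd.DataFrame, truth: GroundTruth, fraction: float, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Give a share of subjects a strictly increasing DS change at a later visit.

    Exactly ``floor(fraction * n_subjects)`` subjects are converted, drawn from
    those whose DS can still increase (DS < 4) and with at least two visits.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    cohort = cohort.copy()
    subjects = cohort["subject_id"].unique()
    n_convert = math.floor(fraction * len(subjects))
    if n_convert == 0:
        return cohort, truth
    rng = _stream(seed, "converters")
    per_sub = cohort.groupby("subject_id").agg(
        ds=("ds", "first"), n_visits=("visit", "nunique")
    )
    eligible = per_sub.index[(per_sub["ds"] < 4) & (per_sub["n_visits"] >= 2)]
    if len(eligible) < n_convert:
        raise ValueError(
            f"cannot plant {n_convert} converters: only {len(eligible)} subjects "
            "have DS < 4 and >= 2 visits"
        )
    chosen = rng.choice(np.sort(eligible.to_numpy()), size=n_convert, replace=False)
    for sid in chosen:
        mask = cohort["subject_id"] == sid
        visits = np.sort(cohort.loc[mask, "visit"].unique())
        switch = rng.choice(visits[1:])
        late = mask & (cohort["visit"] >= switch)
        cohort.loc[late, "ds"] = cohort.loc[late, "ds"] + 1
    new_truth = replace_truth(truth, converter_ids=truth.converter_ids + list(chosen))
    return cohort, new_truth


def plant_outliers(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    fraction: float,
    magnitude: float,
    seed: int,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Shift a share of records by ``magnitude`` within-group sds.

    Each planted record's value is increased by ``magnitude`` times the sample
    sd of its biomarker within its clinical (DS) group, and logged in
    ``truth.outlier_records``.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    if magnitude <= 0:
        raise ValueError("outlier magnitude must be > 0")
    cohort = cohort.copy()
    n_out = math.floor(fraction * len(cohort))
    if n_out == 0:
        return cohort, truth
    rng = _stream(seed, "outliers")
    rows = rng.choice(len(cohort), size=n_out, replace=False)
    group_sd = cohort.groupby(["ds", "biomarker_id"])["value"].transform(
        lambda v: v.std(ddof=1)
    )
    records = []
    for r in rows:
        idx = cohort.index[r]
        cohort.loc[idx, "value"] += magnitude * group_sd.iloc[r]
        records.append(
            (
                cohort.loc[idx, "subject_id"],
                int(cohort.loc[idx, "visit"]),
                cohort.loc[idx, "biomarker_id"],
            )
        )
    new_truth = replace_truth(
        truth, outlier_records=truth.outlier_records + records
    )
    return cohort, new_truth


def replace_truth(truth: GroundTruth, **kwargs) -> GroundTruth:
    data = {
        "planted_factor_order": truth.planted_factor_order,
        "converter_ids": truth.converter_ids,
        "outlier_records": truth.outlier_records,
        "beta_true": truth.beta_true,
    }
    data.update(kwargs)
    return GroundTruth(**data)
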