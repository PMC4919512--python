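"""End-to-end analysis: standardize -> fit/select -> marginalize ->
trajectories -> abnormality -> ordering.

This is the post-QC core that the bootstrap engine resamples and the CLI
drives.  Quality control is applied separately (once, before resampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abnormality import AbnormalityCurve, abnormality_curve, total_abnormality_index
from .cohort import is_imaging
from .model import VARIANTS, FittedBiomarkerModel, fit_all_biomarkers, standardize
from .ordering import (
    FactorCurveSet,
    HierarchicalMatrix,
    VulnerabilityWeights,
    factor_average_curves,
    group_regional_curves,
    hierarchical_matrix,
    rank_factors,
    regional_vulnerability,
)
from .trajectory import (
    TRANSITIONS,
    Trajectory,
    age_grid,
    covariate_domains,
    generate_trajectory,
    marginalize,
    stage_ages,
)


@dataclass
class PipelineResult:
    models: dict[str, FittedBiomarkerModel]
    standardization: pd.DataFrame
    trajectories: dict[tuple[str, str], Trajectory]  # (biomarker, transition)
    curves: dict[str, AbnormalityCurve]  # HC-LOAD abnormality per biomarker
    index_table: pd.DataFrame
    hierarchy: HierarchicalMatrix | None
    vulnerability: VulnerabilityWeights | None
    factor_curves: FactorCurveSet | None
    factor_order: list[str] = field(default_factory=list)
    order_ties: bool = False


def analyze(
    cohort: pd.DataFrame,
    variants: tuple[str, ...] = VARIANTS,
    shape: str = "linear",
    sigmoid_params: tuple[float, float] | None = None,
    weighting: str = "uniform",
    grid: np.ndarray | None = None,
    pre_standardized: bool = False,
) -> PipelineResult:
    """Run the full post-QC analysis on a cohort table.

    ``variants`` selects the candidate model set for BIC selection (all three
    by default).  ``shape`` and ``weighting`` control the DS ramp and the
    covariate marginalization.  Returns every intermediate product.
    """
    grid = age_grid() if grid is None else np.asarray(grid, dtype=float)
    if pre_standardized:
        std_cohort, std_table = cohort, pd.DataFrame(
            {"biomarker_id": sorted(cohort["biomarker_id"].unique())}
        ).assign(mean=0.0, sd=1.0)
    else:
        std_cohort, std_table = standardize(cohort)

    models = fit_all_biomarkers(std_cohort, variants=variants)
    domains = covariate_domains(std_cohort)
    predictors = {
        bm: marginalize(m, domains, weighting=weighting, cohort=std_cohort)
        for bm, m in models.items()
    }

    trajectories: dict[tuple[str, str], Trajectory] = {}
    for bm, pred in predictors.items():
        for transition in TRANSITIONS:
            trajectories[(bm, transition)] = generate_trajectory(
                pred, transition, grid=grid, shape=shape,
                sigmoid_params=sigmoid_params,
            )

    curves = {
        bm: abnormality_curve(
            trajectories[(bm, "HC-LOAD")], trajectories[(bm, "HC-HC")]
        )
        for bm in predictors
    }
    stages = stage_ages(grid, shape=shape, sigmoid_params=sigmoid_params)
    index_table = total_abnormality_index(curves, stage_ages=stages)

    imaging_curves = {bm: c for bm, c in curves.items() if is_imaging(bm)}
    scalar_curves = {bm: c for bm, c in curves.items() if not is_imaging(bm)}
    hierarchy = vulnerability = factor_curves = None
    factor_order: list[str] = []
    ties = False
    if imaging_curves:
        regional = group_regional_curves(imaging_curves)
        hierarchy = hierarchical_matrix(regional)
        vulnerability = regional_vulnerability(
            index_table.loc[list(imaging_curves)]
        )
        factor_curves = factor_average_curves(
            regional, vulnerability, scalar_curves=scalar_curves or None
        )
        factor_order, ties = rank_factors(
            factor_curves, names=sorted(regional)
        )

    return PipelineResult(
        models=models,
        standardization=std_table,
        trajectories=trajectories,
        curves=curves,
        index_table=index_table,
        hierarchy=hierarchy,
        vulnerability=vulnerability,
        factor_curves=factor_curves,
        factor_order=factor_order,
        order_ties=ties,
    )
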