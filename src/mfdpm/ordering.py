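"""Multifactorial ordering: pairwise hierarchy, regional vulnerability,
vulnerability-weighted factor curves and the resulting factor ranking.

Working from per-(factor, region) abnormality curves on a shared age grid:

* the *hierarchical matrix* counts, over all regions and time points, the
  percentage at which one biological factor's abnormality exceeds another's
  (ties split 0.5/0.5 so H[i][j] + H[j][i] = 100 exactly);
* *regional vulnerability* weights each brain region by its summed total
  abnormality index across factors (normalized to sum 1);
* *factor curves* are the vulnerability-weighted regional averages per
  factor — scalar biomarkers join unweighted — normalized by the single
  global maximum so the most abnormal curve peaks at 1;
* the factor ranking orders curves by area under the curve (or by the value
  at a chosen age), giving the data-driven temporal ordering of pathology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abnormality import AbnormalityCurve
from .cohort import split_biomarker_id

RegionalCurves = dict[str, dict[int, AbnormalityCurve]]  # factor -> region -> curve


def group_regional_curves(curves: dict[str, AbnormalityCurve]) -> RegionalCurves:
    """Split a flat curve dict into imaging factor/region structure."""
    out: RegionalCurves = {}
    for bm, curve in curves.items():
        factor, region = split_biomarker_id(bm)
        if region is not None:
            out.setdefault(factor, {})[region] = curve
    return out


def _stack(regional: RegionalCurves) -> tuple[list[str], list[int], np.ndarray]:
    """Validate shared regions/grid; return (factors, regions, A[f, r, t])."""
    factors = sorted(regional)
    if not factors:
        raise ValueError("no imaging factor curves supplied")
    regions = sorted(regional[factors[0]])
    grid = regional[factors[0]][regions[0]].ages
    for f in factors:
        if sorted(regional[f]) != regions:
            raise ValueError(f"factor {f!r} does not cover the common region set")
        for r in regions:
            c = regional[f][r]
            if c.ages.shape != grid.shape or not np.allclose(c.ages, grid):
                raise ValueError(f"curve ({f}, region {r}) is on a different grid")
    A = np.array([[regional[f][r].values for r in regions] for f in factors])
    return factors, regions, A


@dataclass
class HierarchicalMatrix:
    """Factor-by-factor dominance percentages; H[i][j] is how often factor j
    exceeds factor i in abnormality over regions and time points."""

    percentages: pd.DataFrame  # rows i, columns j, reordered by dominance
    ordering: list[str] = field(default_factory=list)


def hierarchical_matrix(regional: RegionalCurves) -> HierarchicalMatrix:
    """Pairwise abnormality dominance over all regions and time points.

    For each region and grid point the strictly larger factor scores 1 (ties
    0.5 each); entries are percentages of region-time points, so
    H[i][j] + H[j][i] = 100 for i != j and the diagonal is 0.  Columns (and
    rows) are reordered so the dominating factors come first.
    """
    factors, _, A = _stack(regional)
    n = len(factors)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            wins = (A[j] > A[i]).mean() + 0.5 * (A[j] == A[i]).mean()
            H[i, j] = 100.0 * wins
    df = pd.DataFrame(H, index=factors, columns=factors)
    dominance = df.sum(axis=0)  # how much each column-factor exceeds the others
    order = dominance.sort_values(ascending=False, kind="stable").index.tolist()
    return HierarchicalMatrix(
        percentages=df.loc[order, order], ordering=order
    )


@dataclass
class VulnerabilityWeights:
    """Per-region weights from summed abnormality across factors (sum 1)."""

    weights: pd.Series  # indexed by region
    raw: pd.Series


def regional_vulnerability(index_table: pd.DataFrame) -> VulnerabilityWeights:
    """Region weights: summed total abnormality index across all factors.

    ``index_table`` is the abnormality index table restricted to imaging
    biomarkers (index = biomarker_id, column ``total``).  Every region must
    carry an index for every factor.
    """
    rows = []
    for bm, total in index_table["total"].items():
        factor, region = split_biomarker_id(bm)
        if region is None:
            continue
        rows.append({"factor": factor, "region": region, "total": total})
    if not rows:
        raise ValueError("index table contains no imaging biomarkers")
    df = pd.DataFrame(rows)
    counts = df.pivot_table(index="region", columns="factor", values="total")
    if counts.isna().any().any():
        missing = [
            (f, int(r))
            for r in counts.index
            for f in counts.columns
            if pd.isna(counts.loc[r, f])
        ]
        raise ValueError(f"missing factor-region index pairs: {missing[:5]}")
    raw = counts.sum(axis=1)
    total = raw.sum()
    weights = raw / total if total > 0 else pd.Series(1.0 / len(raw), index=raw.index)
    return VulnerabilityWeights(weights=weights, raw=raw)


@dataclass
class FactorCurveSet:
    """Normalized average abnormality curve per factor (and scalars)."""

    ages: np.ndarray
    curves: dict[str, np.ndarray]  # all values in [0, 1] after normalization
    global_max: float


def factor_average_curves(
    regional: RegionalCurves,
    weights: VulnerabilityWeights,
    scalar_curves: dict[str, AbnormalityCurve] | None = None,
) -> FactorCurveSet:
    """Vulnerability-weighted factor averages, globally normalized to max 1.

    Scalar biomarker curves (cognitive score, CSF/plasma analytes) pass
    through unweighted and share the same global normalization.
    """
    factors, regions, A = _stack(regional)
    w = weights.weights.reindex(regions)
    if w.isna().any():
        raise ValueError(
            f"weights missing for region(s): {w.index[w.isna()].tolist()}"
        )
    w_arr = w.to_numpy()
    grid = regional[factors[0]][regions[0]].ages
    curves = {f: np.tensordot(w_arr, A[i], axes=1) for i, f in enumerate(factors)}
    if scalar_curves:
        for name, c in scalar_curves.items():
            if c.ages.shape != grid.shape or not np.allclose(c.ages, grid):
                raise ValueError(f"scalar curve {name!r} is on a different grid")
            curves[name] = c.values.copy()
    gmax = max(float(v.max()) for v in curves.values())
    if gmax == 0:
        warnings.warn(
            "all factor curves are zero: skipping normalization", stacklevel=2
        )
        return FactorCurveSet(ages=grid, curves=curves, global_max=0.0)
    return FactorCurveSet(
        ages=grid,
        curves={k: v / gmax for k, v in curves.items()},
        global_max=gmax,
    )


def rank_factors(
    curve_set: FactorCurveSet,
    by: str = "area",
    at_age: float | None = None,
    names: list[str] | None = None,
) -> tuple[list[str], bool]:
    """Rank factors by descending area under the curve (default) or by the
    curve value at ``at_age``.  Returns (ordered names, tie flag); ties are
    broken alphabetically."""
    names = names if names is not None else list(curve_set.curves)
    if by == "area":
        score = {
            k: float(np.trapezoid(curve_set.curves[k], curve_set.ages)) for k in names
        }
    elif by == "at_age":
        if at_age is None:
            raise ValueError("at_age required when ranking by fixed time")
        score = {
            k: float(np.interp(at_age, curve_set.ages, curve_set.curves[k]))
            for k in names
        }
    else:
        raise ValueError(f"unknown ranking mode: {by!r}")
    ordered = sorted(names, key=lambda k: (-score[k], k))
    vals = sorted(score.values(), reverse=True)
    ties = any(a == b for a, b in zip(vals, vals[1:]))
    return ordered, ties


def factor_curves_frame(curve_set: FactorCurveSet) -> pd.DataFrame:
    frames = [
        pd.DataFrame({"factor": k, "age": curve_set.ages, "value": v})
        for k, v in curve_set.curves.items()
    ]
    return pd.concat(frames, ignore_index=True)


def plot_factor_curves(curve_set: FactorCurveSet, ax=None):
    """Basic plot of the normalized factor curves (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for name, vals in curve_set.curves.items():
        ax.plot(curve_set.ages, vals, label=name)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("normalized abnormality")
    ax.set_ylim(-0.02, 1.05)
    ax.legend(fontsize=8)
    return ax
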