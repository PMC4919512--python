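"""Abnormality curves and total / intermediate abnormality indices.

The abnormality of a biomarker along a disease transition is its absolute
deviation, at matched ages, from its own healthy-aging (HC-HC) trajectory:

    A_i(t) = | y_i^disease(t) - y_i^healthy(t) |

Because biomarkers are standardized beforehand, these curves are comparable
across modalities in sd units.  The total abnormality index integrates
A_i(t) over the full aging window and divides by a normalization constant K
(the maximum area across the biomarker set), so the most abnormal biomarker
scores exactly 1.  Intermediate indices truncate the integral at the ages
where the disease ramp reaches the EMCI and LMCI states, capturing
biomarkers that are abnormal early but renormalize later.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory


@dataclass(frozen=True)
class AbnormalityCurve:
    biomarker_id: str
    transition: str
    ages: np.ndarray
    values: np.ndarray  # >= 0, sd units


def abnormality_curve(disease: Trajectory, healthy: Trajectory) -> AbnormalityCurve:
    """Pointwise |disease - healthy| at matched ages.

    ``healthy`` must be the HC-HC trajectory of the same biomarker on the
    same age grid.
    """
    if disease.biomarker_id != healthy.biomarker_id:
        raise ValueError(
            f"biomarker mismatch: {disease.biomarker_id!r} vs {healthy.biomarker_id!r}"
        )
    if disease.ages.shape != healthy.ages.shape or not np.allclose(
        disease.ages, healthy.ages
    ):
        raise ValueError("disease and healthy trajectories use different age grids")
    return AbnormalityCurve(
        biomarker_id=disease.biomarker_id,
        transition=disease.transition,
        ages=disease.ages,
        values=np.abs(disease.values - healthy.values),
    )


def curve_area(curve: AbnormalityCurve, up_to_age: float | None = None) -> float:
    """Trapezoidal area under the curve, optionally truncated at an age."""
    ages, vals = curve.ages, curve.values
    if up_to_age is not None:
        if up_to_age < ages[0] or up_to_age > ages[-1]:
            raise ValueError(
                f"stage age {up_to_age} outside the grid [{ages[0]}, {ages[-1]}]"
            )
        mask = ages <= up_to_age
        ages, vals = ages[mask], vals[mask]
        # include the partial trapezoid up to up_to_age exactly
        if up_to_age > ages[-1]:
            v = np.interp(up_to_age, curve.ages, curve.values)
            ages = np.append(ages, up_to_age)
            vals = np.append(vals, v)
    return float(np.trapezoid(vals, ages))


def intermediate_indices(
    curve: AbnormalityCurve, stage_ages: tuple[float, float], K: float
) -> tuple[float, float]:
    """(EMCI, LMCI) indices: partial areas divided by the shared constant K."""
    emci_age, lmci_age = stage_ages
    if K == 0:
        return 0.0, 0.0
    return (
        curve_area(curve, up_to_age=emci_age) / K,
        curve_area(curve, up_to_age=lmci_age) / K,
    )


def total_abnormality_index(
    curves: dict[str, AbnormalityCurve],
    stage_ages: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Total (and optionally intermediate) abnormality indices for a curve set.

    Returns a table indexed by biomarker with columns ``raw_area``, ``total``
    and, when ``stage_ages`` is given, ``emci`` and ``lmci``; the shared
    normalization constant K (the maximum raw area) is stored in
    ``DataFrame.attrs['K']``.  An all-zero curve set yields zero indices and
    a warning (K is undefined).
    """
    if not curves:
        raise ValueError("empty curve set")
    grids = [c.ages for c in curves.values()]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("curves must share one age grid")
    raw = {bm: curve_area(c) for bm, c in curves.items()}
    K = max(raw.values())
    if K == 0:
        warnings.warn(
            "all abnormality curves are zero: normalization constant undefined, "
            "indices reported as 0",
            stacklevel=2,
        )
    rows = []
    for bm, c in curves.items():
        row = {
            "biomarker_id": bm,
            "raw_area": raw[bm],
            "total": raw[bm] / K if K > 0 else 0.0,
        }
        if stage_ages is not None:
            row["emci"], row["lmci"] = intermediate_indices(c, stage_ages, K)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("biomarker_id")
    out.attrs["K"] = K
    return out


def curves_frame(curves: dict[str, AbnormalityCurve]) -> pd.DataFrame:
    """Long-format table (biomarker, transition, age, abnormality)."""
    frames = [
        pd.DataFrame(
            {
                "biomarker_id": c.biomarker_id,
                "transition": c.transition,
                "age": c.ages,
                "abnormality": c.values,
            }
        )
        for c in curves.values()
    ]
    return pd.concat(frames, ignore_index=True)
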