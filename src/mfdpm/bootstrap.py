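"""Bootstrap confidence bands for trajectories, indices and the ordering.

Subjects (not individual visits) are resampled with replacement, preserving
the within-subject correlation structure the mixed model assumes; the full
post-QC pipeline runs on every replicate and the replicate distribution
yields means and 2.5/97.5 percentile bands.  Reported point estimates are
the replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import VARIANTS, standardize
from .pipeline import analyze

DEFAULT_B = 500


@dataclass
class BandSummary:
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray


@dataclass
class BootstrapResult:
    n_resamples: int
    n_successful: int
    seed: int
    trajectories: dict[tuple[str, str], BandSummary]
    curves: dict[str, BandSummary]
    indices: pd.DataFrame  # per biomarker: mean/lo/hi for total, emci, lmci
    hierarchy: BandSummary | None  # over the factor-by-factor matrix entries
    hierarchy_factors: list[str] = field(default_factory=list)
    order_frequencies: dict[tuple[str, ...], float] = field(default_factory=dict)
    failures: list[tuple[int, str]] = field(default_factory=list)


def resample_subjects(
    cohort: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw subjects with replacement; all of a subject's visits travel
    together.  Duplicated draws get distinct subject ids so they count as
    separate grouping units in the mixed models."""
    subjects = np.sort(cohort["subject_id"].unique())
    draw = rng.choice(subjects, size=len(subjects), replace=True)
    parts = []
    for k, sid in enumerate(draw):
        block = cohort[cohort["subject_id"] == sid].copy()
        block["subject_id"] = f"{sid}#{k}"
        parts.append(block)
    return pd.concat(parts, ignore_index=True)


def _summary(stack: np.ndarray) -> BandSummary:
    return BandSummary(
        mean=stack.mean(axis=0),
        lo=np.percentile(stack, 2.5, axis=0),
        hi=np.percentile(stack, 97.5, axis=0),
    )


def bootstrap_pipeline(
    cohort: pd.DataFrame,
    B: int = DEFAULT_B,
    seed: int = 0,
    variants: tuple[str, ...] = VARIANTS,
    max_failure_fraction: float = 0.2,
    **analyze_kwargs,
) -> BootstrapResult:
    """Resample the (already quality-controlled) cohort B times and summarize.

    A replicate whose fit fails is logged and skipped; if more than
    ``max_failure_fraction`` of replicates fail the whole run errors out.
    Per-replicate seeds derive from the root seed by counter, so results are
    bit-identical across runs (and across serial/parallel execution orders).
    """
    if B < 2:
        raise ValueError("need at least B=2 bootstrap resamples")
    # standardization is a one-time preprocessing step (like QC): do it once
    # on the full cohort so replicates differ only through resampling
    if not analyze_kwargs.pop("pre_standardized", False):
        cohort, _ = standardize(cohort)
    traj_stacks: dict[tuple[str, str], list[np.ndarray]] = {}
    curve_stacks: dict[str, list[np.ndarray]] = {}
    index_rows: list[pd.DataFrame] = []
    matrix_stack: list[np.ndarray] = []
    hierarchy_factors: list[str] = []
    order_counts: dict[tuple[str, ...], int] = {}
    failures: list[tuple[int, str]] = []

    for b in range(B):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(b,))
        )
        sample = resample_subjects(cohort, rng)
        try:
            res = analyze(
                sample, variants=variants, pre_standardized=True,
                **analyze_kwargs,
            )
        except Exception as exc:  # noqa: BLE001 - logged, counted, re-checked below
            failures.append((b, f"{type(exc).__name__}: {exc}"))
            continue
        for key, t in res.trajectories.items():
            traj_stacks.setdefault(key, []).append(t.values)
        for bm, c in res.curves.items():
            curve_stacks.setdefault(bm, []).append(c.values)
        index_rows.append(res.index_table.assign(replicate=b))
        if res.hierarchy is not None:
            factors = sorted(res.hierarchy.percentages.index)
            hierarchy_factors = factors
            matrix_stack.append(
                res.hierarchy.percentages.loc[factors, factors].to_numpy()
            )
        if res.factor_order:
            key = tuple(res.factor_order)
            order_counts[key] = order_counts.get(key, 0) + 1

    n_ok = B - len(failures)
    if len(failures) > max_failure_fraction * B:
        raise RuntimeError(
            f"{len(failures)}/{B} bootstrap replicates failed "
            f"(limit {max_failure_fraction:.0%}); first failure: "
            f"{failures[0][1] if failures else 'n/a'}"
        )

    trajectories = {k: _summary(np.stack(v)) for k, v in traj_stacks.items()}
    curves = {k: _summary(np.stack(v)) for k, v in curve_stacks.items()}

    idx_all = pd.concat(index_rows)
    cols = [c for c in ("total", "emci", "lmci", "raw_area") if c in idx_all.columns]
    grouped = idx_all.groupby("biomarker_id")[cols]
    indices = pd.concat(
        {
            "mean": grouped.mean(),
            "lo": grouped.quantile(0.025),
            "hi": grouped.quantile(0.975),
        },
        axis=1,
    )

    hierarchy = _summary(np.stack(matrix_stack)) if matrix_stack else None
    order_frequencies = {k: v / n_ok for k, v in order_counts.items()}
    return BootstrapResult(
        n_resamples=B,
        n_successful=n_ok,
        seed=seed,
        trajectories=trajectories,
        curves=curves,
        indices=indices,
        hierarchy=hierarchy,
        hierarchy_factors=hierarchy_factors,
        order_frequencies=order_frequencies,
        failures=failures,
    )


def bands_frame(result: BootstrapResult) -> pd.DataFrame:
    """Long-format band table (quantity, key, position, mean, lo, hi)."""
    rows = []
    for (bm, transition), s in result.trajectories.items():
        rows.append(
            pd.DataFrame(
                {
                    "quantity": "trajectory",
                    "key": f"{bm}|{transition}",
                    "position": np.arange(len(s.mean)),
                    "mean": s.mean,
                    "lo": s.lo,
                    "hi": s.hi,
                }
            )
        )
    for bm, s in result.curves.items():
        rows.append(
            pd.DataFrame(
                {
                    "quantity": "abnormality",
                    "key": bm,
                    "position": np.arange(len(s.mean)),
                    "mean": s.mean,
                    "lo": s.lo,
                    "hi": s.hi,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
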