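"""Tidy longitudinal cohort table: schema, validation and biomarker naming.

A cohort is a :class:`pandas.DataFrame` in long format with one row per
(subject, visit, biomarker) observation.  Columns:

``subject_id``  subject identifier (string)
``visit``       non-negative integer visit index
``age``         age in years at the visit
``sex``         0/1
``education``   years of education
``apoe4``       apoe-e4 allele count, 0/1/2
``ds``          ordinal disease state 1=HC, 2=EMCI, 3=LMCI, 4=LOAD
``biomarker_id`` biomarker identifier (see below)
``value``       the measurement (real)

Imaging biomarkers are named ``"<factor>__r<region>"`` (e.g. ``amyloid__r07``)
so that the biological factor and the grey-matter region can be recovered;
scalar biomarkers (cognitive score, CSF/plasma analytes) use their plain name.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COHORT_COLUMNS = [
    "subject_id",
    "visit",
    "age",
    "sex",
    "education",
    "apoe4",
    "ds",
    "biomarker_id",
    "value",
]

COVARIATE_COLUMNS = ["age", "ds", "sex", "education", "apoe4"]

DS_LABELS = {1: "HC", 2: "EMCI", 3: "LMCI", 4: "LOAD"}

_REGION_SEP = "__r"


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the documented schema."""


def imaging_biomarker_id(factor: str, region: int) -> str:
    """Compose the biomarker identifier for ``factor`` measured at ``region``."""
    return f"{factor}{_REGION_SEP}{region:03d}"


def split_biomarker_id(biomarker_id: str) -> tuple[str, int | None]:
    """Return ``(factor, region)`` for imaging ids, ``(name, None)`` for scalars."""
    if _REGION_SEP in biomarker_id:
        factor, region = biomarker_id.rsplit(_REGION_SEP, 1)
        try:
            return factor, int(region)
        except ValueError:
            return biomarker_id, None
    return biomarker_id, None


def is_imaging(biomarker_id: str) -> bool:
    return split_biomarker_id(biomarker_id)[1] is not None


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the schema; return it (re-typed).

    Raises :class:`CohortValidationError` with a descriptive message naming
    the offending column / rows.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"cohort table is missing required column(s): {', '.join(missing)}"
        )
    df = df.loc[:, COHORT_COLUMNS].copy()
    for col, dtype in [
        ("visit", int),
        ("age", float),
        ("sex", int),
        ("education", float),
        ("apoe4", int),
        ("ds", int),
        ("value", float),
    ]:
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(
                f"column '{col}' contains non-numeric or malformed values: {exc}"
            ) from exc
    df["subject_id"] = df["subject_id"].astype(str)
    df["biomarker_id"] = df["biomarker_id"].astype(str)

    if (df["visit"] < 0).any():
        raise CohortValidationError("column 'visit' contains negative indices")
    bad_ds = ~df["ds"].isin([1, 2, 3, 4])
    if bad_ds.any():
        rows = df.index[bad_ds][:5].tolist()
        raise CohortValidationError(f"column 'ds' outside 1..4 at rows {rows}")
    bad_sex = ~df["sex"].isin([0, 1])
    if bad_sex.any():
        raise CohortValidationError("column 'sex' must be coded 0/1")
    bad_apoe = ~df["apoe4"].isin([0, 1, 2])
    if bad_apoe.any():
        raise CohortValidationError("column 'apoe4' must be an allele count 0/1/2")

    dup = df.duplicated(subset=["subject_id", "visit", "biomarker_id"])
    if dup.any():
        rows = df.index[dup][:5].tolist()
        raise CohortValidationError(
            f"duplicate (subject_id, visit, biomarker_id) records at rows {rows}"
        )

    # age strictly increasing across visits within subject
    per_visit = df.drop_duplicates(["subject_id", "visit"]).sort_values(
        ["subject_id", "visit"]
    )
    for sid, grp in per_visit.groupby("subject_id", sort=False):
        ages = grp["age"].to_numpy()
        if len(ages) > 1 and not np.all(np.diff(ages) > 0):
            raise CohortValidationError(
                f"subject '{sid}': age must be strictly increasing across visits"
            )
    return df


def subject_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per subject-visit with the risk-factor covariates."""
    return (
        cohort.drop_duplicates(["subject_id", "visit"])
        .loc[:, ["subject_id", "visit"] + COVARIATE_COLUMNS]
        .sort_values(["subject_id", "visit"])
        .reset_index(drop=True)
    )


def wide_values(cohort: pd.DataFrame, biomarker_ids=None) -> pd.DataFrame:
    """Pivot to one row per subject-visit, one column per biomarker."""
    df = cohort
    if biomarker_ids is not None:
        df = df[df["biomarker_id"].isin(list(biomarker_ids))]
    return df.pivot_table(
        index=["subject_id", "visit"],
        columns="biomarker_id",
        values="value",
        aggfunc="first",
    )
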