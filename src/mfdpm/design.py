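"""Fixed-effects design for the per-biomarker progression model.

Five risk factors — age, disease state (DS), sex, education, apoe-e4 allele
count — enter as main effects together with all 10 unordered pairwise
products, plus an intercept: 16 columns in a fixed, deterministic order.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

MAIN_EFFECTS = ["age", "ds", "sex", "education", "apoe4"]
INTERACTIONS = [f"{a}:{b}" for a, b in combinations(MAIN_EFFECTS, 2)]
DESIGN_COLUMNS = ["intercept"] + MAIN_EFFECTS + INTERACTIONS


def design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Build the 16-column design matrix from a covariate table.

    ``covariates`` must contain the five risk-factor columns; rows map one-to-one
    to observations.  Raises ``ValueError`` naming any missing covariate.
    """
    missing = [c for c in MAIN_EFFECTS if c not in covariates.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {', '.join(missing)}")
    n = len(covariates)
    X = np.empty((n, len(DESIGN_COLUMNS)))
    X[:, 0] = 1.0
    for j, name in enumerate(MAIN_EFFECTS, start=1):
        X[:, j] = covariates[name].to_numpy(dtype=float)
    for j, name in enumerate(INTERACTIONS, start=1 + len(MAIN_EFFECTS)):
        a, b = name.split(":")
        X[:, j] = covariates[a].to_numpy(dtype=float) * covariates[b].to_numpy(
            dtype=float
        )
    return X
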