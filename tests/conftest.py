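import numpy as np
import pandas as pd
import pytest

import mfdpm
from mfdpm.design import DESIGN_COLUMNS


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects, 3 visits, 2 factors x 2 regions + 1 scalar biomarker."""
    cfg = mfdpm.SyntheticConfig(
        n_subjects=40,
        n_visits=3,
        n_regions=2,
        factor_names=("amyloid", "vascular"),
        scalar_biomarker_names=("mmse",),
        noise_sd=0.5,
        seed=11,
    )
    cohort, truth = mfdpm.generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture()
def beta_index():
    return {name: i for i, name in enumerate(DESIGN_COLUMNS)}


def make_covariates(n_sub, n_vis, seed=0, ds_values=(1, 2, 3, 4)):
    """Bare covariate frame (no biomarkers) for direct fit tests."""
    rng = np.random.default_rng(seed)
    sub = np.repeat(np.arange(n_sub), n_vis)
    visit = np.tile(np.arange(n_vis), n_sub)
    age = rng.uniform(40, 70, n_sub)[sub] + visit
    return pd.DataFrame(
        {
            "subject_id": np.char.add("S", sub.astype(str)),
            "visit": visit,
            "age": age,
            "sex": rng.integers(0, 2, n_sub)[sub],
            "education": rng.integers(6, 21, n_sub)[sub].astype(float),
            "apoe4": rng.choice([0, 1, 2], n_sub, p=[0.6, 0.3, 0.1])[sub],
            "ds": rng.choice(ds_values, n_sub)[sub],
        }
    )
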