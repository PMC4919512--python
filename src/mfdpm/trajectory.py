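"""Covariate marginalization and characteristic trajectories.

A fitted biomarker model predicts from age, disease state (DS) and three
nuisance covariates (sex, education, apoe4).  Marginalizing averages the
fixed-effects predictor over the nuisance covariates — uniformly over each
covariate's range/categories by default, or with empirical frequencies —
leaving a function g(age, DS) only.  Random effects have population mean
zero and drop out.

Characteristic trajectories evaluate g on a weekly age grid spanning a
30-year aging window (40-70 years, 1560 points) while DS ramps from the
healthy state (1) to the transition's terminal state (2, 3 or 4), linearly
or along a logistic (sigmoid) path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .model import FittedBiomarkerModel

MARGINALIZED = ("sex", "education", "apoe4")

TRANSITIONS = {"HC-HC": 1.0, "HC-EMCI": 2.0, "HC-LMCI": 3.0, "HC-LOAD": 4.0}

AGE_START, AGE_END, N_GRID = 40.0, 70.0, 1560  # weekly over 30 years


def age_grid(start: float = AGE_START, end: float = AGE_END, n: int = N_GRID):
    """The inclusive weekly age grid (default 1560 points over 40-70 y)."""
    return np.linspace(start, end, n)


@dataclass(frozen=True)
class CovariateDomain:
    """Range (continuous) or category set (discrete) of one nuisance covariate."""

    name: str
    kind: str  # "continuous" | "categorical"
    values: tuple[float, ...]  # (lo, hi) or category levels

    def grid(self, n: int = 21) -> np.ndarray:
        if self.kind == "continuous":
            return np.linspace(self.values[0], self.values[1], n)
        return np.asarray(self.values, dtype=float)

    def mean(self) -> float:
        if self.kind == "continuous":
            return 0.5 * (self.values[0] + self.values[1])
        return float(np.mean(self.values))


def covariate_domains(cohort: pd.DataFrame) -> dict[str, CovariateDomain]:
    """Observed domains of the marginalized covariates (min-to-max / categories)."""
    sub = cohort.drop_duplicates(["subject_id", "visit"])
    return {
        "sex": CovariateDomain(
            "sex", "categorical", tuple(sorted(sub["sex"].unique().astype(float)))
        ),
        "education": CovariateDomain(
            "education",
            "continuous",
            (float(sub["education"].min()), float(sub["education"].max())),
        ),
        "apoe4": CovariateDomain(
            "apoe4", "categorical", tuple(sorted(sub["apoe4"].unique().astype(float)))
        ),
    }


@dataclass(frozen=True)
class MarginalPredictor:
    """g(age, DS): the covariate-averaged fixed-effects predictor.

    For the linear predictor with pairwise interactions the covariate average
    collapses to four effective coefficients::

        g(age, ds) = a0 + a_age * age + a_ds * ds + a_age_ds * age * ds
    """

    biomarker_id: str
    a0: float
    a_age: float
    a_ds: float
    a_age_ds: float
    provenance: dict = field(default_factory=dict, compare=False)

    def __call__(self, age, ds):
        age = np.asarray(age, dtype=float)
        ds = np.asarray(ds, dtype=float)
        return self.a0 + self.a_age * age + self.a_ds * ds + self.a_age_ds * age * ds


def _moments(
    domains: dict[str, CovariateDomain],
    weighting: str,
    cohort: pd.DataFrame | None,
) -> tuple[dict[str, float], dict[frozenset, float]]:
    """First moments and pairwise product moments of the nuisance covariates."""
    if weighting == "uniform":
        m1 = {c: domains[c].mean() for c in MARGINALIZED}
        # independent uniform weighting over each domain: products factorize
        m2 = {
            frozenset((a, b)): m1[a] * m1[b] for a, b in combinations(MARGINALIZED, 2)
        }
    elif weighting == "empirical":
        if cohort is None:
            raise ValueError("empirical weighting requires the cohort table")
        sub = cohort.drop_duplicates(["subject_id", "visit"])
        m1 = {c: float(sub[c].mean()) for c in MARGINALIZED}
        m2 = {
            frozenset((a, b)): float((sub[a] * sub[b]).mean())
            for a, b in combinations(MARGINALIZED, 2)
        }
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")
    return m1, m2


def marginalize(
    model: FittedBiomarkerModel,
    domains: dict[str, CovariateDomain],
    weighting: str = "uniform",
    cohort: pd.DataFrame | None = None,
) -> MarginalPredictor:
    """Average the fixed-effects predictor over sex, education and apoe4.

    ``weighting='uniform'`` weights each covariate uniformly from its minimum
    to its maximum (categories equally); ``'empirical'`` uses observed
    frequencies (joint, so correlated covariates are handled exactly).
    """
    for c in MARGINALIZED:
        if c not in domains or len(domains[c].values) == 0:
            raise ValueError(f"empty or missing domain for covariate '{c}'")
    beta = model.beta

    def b(name: str) -> float:
        if name in beta.index:
            return float(beta[name])
        a, sep, c = name.partition(":")
        alt = f"{c}:{a}" if sep else name
        return float(beta[alt]) if alt in beta.index else 0.0

    m1, m2 = _moments(domains, weighting, cohort)
    a0 = b("intercept") + sum(b(c) * m1[c] for c in MARGINALIZED)
    a0 += sum(
        b(f"{a}:{c}") * m2[frozenset((a, c))] for a, c in combinations(MARGINALIZED, 2)
    )
    a_age = b("age") + sum(b(f"age:{c}") * m1[c] for c in MARGINALIZED)
    a_ds = b("ds") + sum(b(f"ds:{c}") * m1[c] for c in MARGINALIZED)
    return MarginalPredictor(
        biomarker_id=model.biomarker_id,
        a0=a0,
        a_age=a_age,
        a_ds=a_ds,
        a_age_ds=b("age:ds"),
        provenance={
            "weighting": weighting,
            "covariate_means": m1,
            "marginalized": list(MARGINALIZED),
        },
    )


def ds_path(
    transition: str,
    grid: np.ndarray,
    shape: str = "linear",
    sigmoid_params: tuple[float, float] | None = None,
) -> np.ndarray:
    """DS(t) along a clinical transition on the age grid.

    Linear: DS interpolates from 1 at the grid start to the terminal state at
    the grid end.  Sigmoid: a logistic ramp between the same endpoints
    (normalized so the endpoints are met exactly); ``sigmoid_params`` is
    (midpoint age, steepness per year), default midpoint mid-grid with a
    5%-95% rise spanning 20 years.
    """
    if transition not in TRANSITIONS:
        raise ValueError(
            f"unknown transition {transition!r}; expected one of {list(TRANSITIONS)}"
        )
    grid = np.asarray(grid, dtype=float)
    terminal = TRANSITIONS[transition]
    if terminal == 1.0:
        return np.ones_like(grid)
    lo, hi = grid[0], grid[-1]
    if shape == "linear":
        frac = (grid - lo) / (hi - lo)
    elif shape == "sigmoid":
        if sigmoid_params is None:
            mid = 0.5 * (lo + hi)
            steep = 2.0 * np.log(19.0) / 20.0  # 5% -> 95% over 20 years
        else:
            mid, steep = sigmoid_params
        s = 1.0 / (1.0 + np.exp(-steep * (grid - mid)))
        s0 = 1.0 / (1.0 + np.exp(-steep * (lo - mid)))
        s1 = 1.0 / (1.0 + np.exp(-steep * (hi - mid)))
        frac = (s - s0) / (s1 - s0)
    else:
        raise ValueError(f"unknown ds path shape: {shape!r}")
    return 1.0 + (terminal - 1.0) * frac


@dataclass(frozen=True)
class Trajectory:
    """A biomarker's characteristic curve along one clinical transition."""

    biomarker_id: str
    transition: str
    ages: np.ndarray
    ds: np.ndarray
    values: np.ndarray


def generate_trajectory(
    predictor: MarginalPredictor,
    transition: str,
    grid: np.ndarray | None = None,
    shape: str = "linear",
    sigmoid_params: tuple[float, float] | None = None,
) -> Trajectory:
    """Evaluate the marginal predictor along a clinical transition."""
    grid = age_grid() if grid is None else np.asarray(grid, dtype=float)
    ds = ds_path(transition, grid, shape=shape, sigmoid_params=sigmoid_params)
    return Trajectory(
        biomarker_id=predictor.biomarker_id,
        transition=transition,
        ages=grid,
        ds=ds,
        values=predictor(grid, ds),
    )


def stage_ages(
    grid: np.ndarray,
    shape: str = "linear",
    sigmoid_params: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Ages at which DS first reaches the EMCI (2) and LMCI (3) states
    on the HC-LOAD ramp (50 and 60 years for the default linear path)."""
    ds = ds_path("HC-LOAD", grid, shape=shape, sigmoid_params=sigmoid_params)
    emci = float(grid[np.searchsorted(ds, 2.0)])
    lmci = float(grid[np.searchsorted(ds, 3.0)])
    return emci, lmci


def trajectories_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Long-format table (biomarker, transition, age, ds, value)."""
    frames = [
        pd.DataFrame(
            {
                "biomarker_id": t.biomarker_id,
                "transition": t.transition,
                "age": t.ages,
                "ds": t.ds,
                "value": t.values,
            }
        )
        for t in trajectories
    ]
    return pd.concat(frames, ignore_index=True)
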