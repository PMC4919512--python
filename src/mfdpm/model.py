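"""Per-biomarker model fitting: standardization, three model variants, BIC.

Each standardized biomarker is modelled as a linear function of the 16-column
risk-factor design (intercept, five mains, ten pairwise interactions) under
three nested variants of the within-subject error structure:

``fixed_robust``            purely fixed effects, fitted by iteratively
                            reweighted least squares with Tukey bisquare
                            weights (robust to gross measurement outliers);
``mixed_intercept``         adds a subject-level random intercept, fitted by
                            maximum likelihood;
``mixed_intercept_slope``   adds a subject-level random age slope as well.

The variant retained for a biomarker is the one minimizing
``BIC = k ln(n) - 2 logL`` with ``k`` the number of free parameters.  For the
robust variant the Gaussian log-likelihood is evaluated at the robust
coefficients with the MLE residual variance — an approximation that makes the
three variants comparable on one scale (on clean data the robust fit
coincides with OLS, whose Gaussian likelihood is exact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import DESIGN_COLUMNS, design_matrix
from .lmm import profile_ml

VARIANTS = ("fixed_robust", "mixed_intercept", "mixed_intercept_slope")

_LL_FLOOR_VAR = 1e-12  # variance floor keeping BIC finite on noiseless data


@dataclass
class FittedBiomarkerModel:
    biomarker_id: str
    variant: str
    beta: pd.Series  # indexed by design column names
    random_sd: tuple[float, float] | None  # (intercept sd, age-slope sd)
    residual_sd: float
    log_likelihood: float
    bic: float
    n_obs: int
    n_params: int
    standardization: tuple[float, float] | None = None  # (mean, sd)
    warnings: tuple[str, ...] = ()


def standardize(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score every biomarker across all retained subject-visits.

    Returns the transformed cohort and a table ``(biomarker_id, mean, sd)``
    for inverse mapping.  Constant biomarkers (sd == 0) cannot be scaled and
    are excluded with a warning.
    """
    stats = (
        cohort.groupby("biomarker_id")["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    constant = stats.loc[~(stats["sd"] > 0), "biomarker_id"].tolist()
    if constant:
        warnings.warn(
            f"excluding constant biomarker(s) with zero sd: {constant}",
            stacklevel=2,
        )
        cohort = cohort[~cohort["biomarker_id"].isin(constant)]
        stats = stats[~stats["biomarker_id"].isin(constant)]
    merged = cohort.merge(stats, on="biomarker_id", how="left")
    merged["value"] = (merged["value"] - merged["mean"]) / merged["sd"]
    out = merged.drop(columns=["mean", "sd"])
    return out, stats.reset_index(drop=True)


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear column(s): {bad or 'unresolved'}"
        )


def _gaussian_ll(resid: np.ndarray) -> tuple[float, float]:
    """Gaussian log-likelihood at MLE variance; returns (ll, sigma2)."""
    n = resid.size
    sigma2 = max(float(np.mean(resid**2)), _LL_FLOOR_VAR)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + np.mean(resid**2) / sigma2)
    return float(ll), sigma2


def _bic(ll: float, k: int, n: int) -> float:
    return k * np.log(n) - 2.0 * ll


def fit_fixed_robust(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    biomarker_id: str = "",
    tol: float = 1e-8,
    maxiter: int = 50,
) -> FittedBiomarkerModel:
    """Variant (i): robust M-estimation with bisquare weights.

    Iterates reweighted least squares until the relative coefficient change
    drops below ``tol`` (or ``maxiter`` sweeps).  On data with negligible
    residual scale the OLS solution is returned directly (the M-estimator is
    undefined when the MAD scale is zero).
    """
    names = names or DESIGN_COLUMNS
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need n_obs > n_params for the fixed-effects fit")
    _check_design(X, names)

    ols_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ols_resid = y - X @ ols_beta
    scale = sm.robust.scale.mad(ols_resid, center=0)
    notes: tuple[str, ...] = ()
    if scale < 1e-10 * max(1.0, float(np.abs(y).max())):
        beta = ols_beta
        resid = ols_resid
        notes = ("zero residual scale: returned the exact least-squares fit",)
    else:
        rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight())
        res = rlm.fit(conv="coefs", tol=tol, maxiter=maxiter)
        beta = np.asarray(res.params)
        resid = y - X @ beta
    ll, sigma2 = _gaussian_ll(resid)
    k = X.shape[1] + 1  # betas + residual variance
    return FittedBiomarkerModel(
        biomarker_id=biomarker_id,
        variant="fixed_robust",
        beta=pd.Series(beta, index=names),
        random_sd=None,
        residual_sd=float(np.sqrt(sigma2)),
        log_likelihood=ll,
        bic=_bic(ll, k, len(y)),
        n_obs=len(y),
        n_params=k,
        warnings=notes,
    )


def fit_mixed(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    age: np.ndarray | None = None,
    random: str = "intercept",
    names: list[str] | None = None,
    biomarker_id: str = "",
    maxiter: int = 200,
) -> FittedBiomarkerModel:
    """Variants (ii)/(iii): linear mixed model by maximum likelihood.

    ``random='intercept'`` fits a subject random intercept; ``'intercept_slope'``
    additionally a random age slope (``age`` required, full 2x2 random-effects
    covariance).  ML (not REML) so BIC is comparable across variants.
    A variance estimated at the 0 boundary is allowed and reported.
    """
    names = names or DESIGN_COLUMNS
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need n_obs > n_params for the mixed-effects fit")
    _check_design(X, names)
    if random not in ("intercept", "intercept_slope"):
        raise ValueError(f"unknown random-effects structure: {random!r}")
    age_center = 0.0
    if random == "intercept_slope":
        if age is None:
            raise ValueError("age vector required for the random-slope variant")
        age = np.asarray(age, float)
        # center age in the random-effects design: an exact reparameterization
        # (the full covariance absorbs the shift) that fixes the conditioning
        # of the [1, age] pair; the covariance is mapped back to raw-age units
        age_center = float(age.mean())
        exog_re = np.column_stack([np.ones_like(y), age - age_center])
        n_re = 3  # 2 variances + covariance
    else:
        exog_re = np.ones((len(y), 1))
        n_re = 1

    notes: list[str] = []
    counts = pd.Series(groups).value_counts()
    if (counts <= 1).all():
        notes.append(
            "single visit per subject: random intercept variance is not "
            "identifiable against residual noise"
        )
    res = profile_ml(y, X, exog_re, np.asarray(groups), maxiter=maxiter)
    cov_re = np.atleast_2d(res.cov_re)
    if random == "intercept_slope" and age_center != 0.0:
        # map (intercept, slope) covariance from centered to raw-age units:
        # b0_raw = b0_c - c * b1, so Sigma_raw = T Sigma_c T', T = [[1,-c],[0,1]]
        T = np.array([[1.0, -age_center], [0.0, 1.0]])
        cov_re = T @ cov_re @ T.T
    sds = np.sqrt(np.clip(np.diag(cov_re), 0.0, None))
    if np.any(np.diag(cov_re) < 1e-8):
        notes.append("variance component estimated at the 0 boundary")
    random_sd = (float(sds[0]), float(sds[1]) if len(sds) > 1 else 0.0)
    k = X.shape[1] + n_re + 1
    ll = float(res.llf)
    return FittedBiomarkerModel(
        biomarker_id=biomarker_id,
        variant="mixed_intercept" if random == "intercept" else "mixed_intercept_slope",
        beta=pd.Series(res.beta, index=names),
        random_sd=random_sd,
        residual_sd=float(np.sqrt(res.sigma2)),
        log_likelihood=ll,
        bic=_bic(ll, k, len(y)),
        n_obs=len(y),
        n_params=k,
        warnings=tuple(notes),
    )


def select_model_bic(candidates: list[FittedBiomarkerModel]) -> FittedBiomarkerModel:
    """Return the candidate minimizing BIC; ties go to the fewest parameters."""
    if not candidates:
        raise ValueError("no candidate models supplied")
    n_set = {m.n_obs for m in candidates}
    if len(n_set) != 1:
        raise ValueError(f"candidates fitted on different n_obs: {sorted(n_set)}")
    return min(candidates, key=lambda m: (m.bic, m.n_params))


def fit_biomarker(
    covariates: pd.DataFrame,
    y: np.ndarray,
    biomarker_id: str = "",
    variants: tuple[str, ...] = VARIANTS,
) -> FittedBiomarkerModel:
    """Fit the requested variants for one biomarker and select by BIC.

    ``covariates`` holds one row per observation (subject_id + the five risk
    factors, aligned with ``y``).
    """
    X = design_matrix(covariates)
    groups = covariates["subject_id"].to_numpy()
    age = covariates["age"].to_numpy(dtype=float)
    fits: list[FittedBiomarkerModel] = []
    for variant in variants:
        if variant == "fixed_robust":
            fits.append(fit_fixed_robust(X, y, biomarker_id=biomarker_id))
        elif variant == "mixed_intercept":
            fits.append(
                fit_mixed(X, y, groups, random="intercept", biomarker_id=biomarker_id)
            )
        elif variant == "mixed_intercept_slope":
            fits.append(
                fit_mixed(
                    X, y, groups, age=age, random="intercept_slope",
                    biomarker_id=biomarker_id,
                )
            )
        else:
            raise ValueError(f"unknown model variant: {variant!r}")
    return select_model_bic(fits)


def fit_all_biomarkers(
    cohort: pd.DataFrame, variants: tuple[str, ...] = VARIANTS
) -> dict[str, FittedBiomarkerModel]:
    """Standardized cohort -> BIC-selected fit per biomarker."""
    fits = {}
    for bm, grp in cohort.groupby("biomarker_id", sort=True):
        fits[bm] = fit_biomarker(
            grp, grp["value"].to_numpy(dtype=float), biomarker_id=bm,
            variants=variants,
        )
    return fits


def fits_to_frame(fits: dict[str, FittedBiomarkerModel]) -> pd.DataFrame:
    """Serialize fit results to one tidy row per biomarker."""
    rows = []
    for bm, m in fits.items():
        row = {
            "biomarker_id": bm,
            "variant": m.variant,
            "residual_sd": m.residual_sd,
            "log_likelihood": m.log_likelihood,
            "bic": m.bic,
            "n_obs": m.n_obs,
            "random_intercept_sd": m.random_sd[0] if m.random_sd else np.nan,
            "random_slope_sd": m.random_sd[1] if m.random_sd else np.nan,
        }
        row.update({f"beta_{k}": v for k, v in m.beta.items()})
        if m.standardization is not None:
            row["std_mean"], row["std_sd"] = m.standardization
        rows.append(row)
    return pd.DataFrame(rows)
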