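"""Three-step cohort homogeneity / quality control.

(i)   remove subjects whose clinical diagnosis changes across visits
      (converters);
(ii)  score how typical each subject's multimodal profile is of its assigned
      clinical group (leave-one-subject-out Gaussian class-conditional
      likelihood, rank-normalized within group) and drop subjects below the
      10th within-group percentile;
(iii) flag and remove multivariate outlier records via the squared
      Mahalanobis distance against a chi-square reference (P < 0.05 by
      default), per clinical group, per biomarker or per imaging modality
      across all regions.

Steps (i)-(ii) target diagnostic heterogeneity, step (iii) measurement
noise.  The pipeline order is fixed; cohort sizes are monotone
non-increasing through the steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import LedoitWolf

from .cohort import is_imaging, split_biomarker_id, wide_values


@dataclass
class QCReport:
    removed_converters: list[str] = field(default_factory=list)
    likelihood_scores: pd.Series | None = None
    removed_low_likelihood: list[str] = field(default_factory=list)
    outlier_flags: pd.DataFrame | None = None
    retained_sizes: dict[str, int] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["# quality-control report", ""]
        lines.append("## step (i): converter removal")
        lines.append(f"removed subjects: {len(self.removed_converters)}")
        lines.append("## step (ii): diagnosis likelihood filter")
        lines.append(f"removed subjects: {len(self.removed_low_likelihood)}")
        lines.append("## step (iii): Mahalanobis outlier records")
        n_flags = 0 if self.outlier_flags is None else len(self.outlier_flags)
        lines.append(f"flagged records: {n_flags}")
        lines.append("")
        lines.append("retained cohort sizes (subjects): " + str(self.retained_sizes))
        return "\n".join(lines)


def remove_converters(cohort: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Step (i): drop every subject with more than one distinct DS value."""
    n_ds = cohort.groupby("subject_id")["ds"].nunique()
    converters = n_ds.index[n_ds > 1].tolist()
    retained = cohort[~cohort["subject_id"].isin(converters)].reset_index(drop=True)
    report = QCReport(
        removed_converters=converters,
        retained_sizes={
            "before": int(n_ds.size),
            "after_converters": int(n_ds.size - len(converters)),
        },
    )
    return retained, report


def _subject_features(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject multimodal feature vector: visit-averaged, region-averaged
    value per imaging factor plus each scalar biomarker."""
    df = cohort.copy()
    parsed = df["biomarker_id"].map(split_biomarker_id)
    df["feature"] = [factor for factor, _ in parsed]
    feats = df.groupby(["subject_id", "feature"])["value"].mean().unstack()
    return feats


def diagnosis_likelihood_scores(cohort: pd.DataFrame) -> pd.Series:
    """Step (ii) scores in (0, 1]: how typical each subject is of its group.

    For each subject, a Gaussian is fitted to its clinical group's feature
    vectors *excluding the subject* (leave-one-subject-out); the subject's
    log-density under that Gaussian is rank-normalized within the group, so
    the most typical subject of each group scores 1 and the least typical
    1/n_group.
    """
    feats = _subject_features(cohort)
    groups = cohort.groupby("subject_id")["ds"].first()
    d = feats.shape[1]
    scores = {}
    for ds_value, members in groups.groupby(groups):
        ids = members.index.tolist()
        if len(ids) <= d + 1:
            raise ValueError(
                f"clinical group DS={ds_value} has {len(ids)} subjects; "
                f"too few to estimate a {d}-dimensional covariance"
            )
        Xg = feats.loc[ids].to_numpy()
        logpdf = np.empty(len(ids))
        for i in range(len(ids)):
            rest = np.delete(Xg, i, axis=0)
            mu = rest.mean(axis=0)
            cov = np.cov(rest, rowvar=False)
            cov = _regularize(cov, rest.shape[0], rest)
            logpdf[i] = stats.multivariate_normal.logpdf(
                Xg[i], mean=mu, cov=cov, allow_singular=True
            )
        ranks = stats.rankdata(logpdf, method="average")
        for sid, r in zip(ids, ranks):
            scores[sid] = r / len(ids)
    return pd.Series(scores, name="likelihood_score").sort_index()


def filter_low_likelihood(
    cohort: pd.DataFrame,
    scores: pd.Series,
    percentile: float = 10.0,
    report: QCReport | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Step (ii): remove subjects scoring strictly below the within-group
    percentile (ties kept, so all-equal scores remove nobody)."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    subjects = cohort["subject_id"].unique()
    missing = sorted(set(subjects) - set(scores.index))
    if missing:
        raise ValueError(f"scores missing for subject(s): {missing[:10]}")
    groups = cohort.groupby("subject_id")["ds"].first()
    removed: list[str] = []
    for _, members in groups.groupby(groups):
        ids = members.index.to_numpy()
        s = scores.loc[ids]
        cut = np.percentile(s.to_numpy(), percentile)
        removed.extend(ids[(s < cut).to_numpy()])
    retained = cohort[~cohort["subject_id"].isin(removed)].reset_index(drop=True)
    report = report or QCReport()
    report.likelihood_scores = scores
    report.removed_low_likelihood = sorted(removed)
    report.retained_sizes["after_likelihood"] = int(len(subjects) - len(removed))
    return retained, report


def _regularize(cov: np.ndarray, n: int, X: np.ndarray | None = None) -> np.ndarray:
    """Ledoit-Wolf shrinkage when the empirical covariance is ill-conditioned."""
    cov = np.atleast_2d(cov)
    d = cov.shape[0]
    cond_bad = n <= d or np.linalg.cond(cov) > 1e10
    if cond_bad:
        if X is None:
            raise ValueError(
                "singular covariance: enable shrinkage by passing the data"
            )
        cov = LedoitWolf().fit(X).covariance_
    return cov


def detect_outliers_mahalanobis(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    scope: str = "per-modality",
    report: QCReport | None = None,
    shrinkage: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Step (iii): flag records whose squared Mahalanobis distance within
    their clinical group exceeds the chi-square 1-alpha quantile.

    ``scope='per-biomarker'`` tests each biomarker separately (d = 1);
    ``'per-modality'`` tests each imaging factor's full region vector per
    subject-visit (d = number of regions, shrinkage covariance when n <= d)
    while scalar biomarkers are still tested individually.  Flagged values
    are removed for that biomarker/modality only; the subject's other data
    are kept.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if scope not in ("per-biomarker", "per-modality"):
        raise ValueError(f"unknown outlier scope: {scope!r}")
    flags: list[dict] = []
    drop_keys: list[tuple[str, int, str]] = []  # (subject, visit, biomarker)

    if scope == "per-biomarker":
        feature_sets = [([bm], [bm]) for bm in sorted(cohort["biomarker_id"].unique())]
    else:
        imaging = sorted(
            {bm for bm in cohort["biomarker_id"].unique() if is_imaging(bm)}
        )
        factors: dict[str, list[str]] = {}
        for bm in imaging:
            factors.setdefault(split_biomarker_id(bm)[0], []).append(bm)
        scalars = sorted(
            bm for bm in cohort["biomarker_id"].unique() if not is_imaging(bm)
        )
        feature_sets = [(bms, bms) for bms in factors.values()]
        feature_sets += [([bm], [bm]) for bm in scalars]

    for ds_value, grp in cohort.groupby("ds"):
        for bms, _ in feature_sets:
            wide = wide_values(grp, bms).dropna()
            if wide.empty:
                continue
            X = wide.to_numpy()
            n, d = X.shape
            if n <= d and not shrinkage:
                raise ValueError(
                    f"group DS={ds_value}, features {bms[:2]}...: covariance is "
                    "singular (n <= d); enable shrinkage"
                )
            if n < 3:
                continue  # too few records to define a distance
            mu = X.mean(axis=0)
            cov = np.cov(X, rowvar=False)
            cov = _regularize(np.atleast_2d(cov), n, X if shrinkage else None)
            prec = np.linalg.pinv(cov)
            delta = X - mu
            d2 = np.einsum("ij,jk,ik->i", delta, prec, delta)
            thresh = stats.chi2.ppf(1 - alpha, df=d)
            pvals = stats.chi2.sf(d2, df=d)
            label = split_biomarker_id(bms[0])[0] if len(bms) > 1 else bms[0]
            for (sid, visit), dist2, p in zip(wide.index, d2, pvals):
                if dist2 > thresh:
                    flags.append(
                        {
                            "subject_id": sid,
                            "visit": int(visit),
                            "ds": int(ds_value),
                            "feature": label,
                            "squared_distance": float(dist2),
                            "p_value": float(p),
                        }
                    )
                    drop_keys.extend((sid, int(visit), bm) for bm in bms)

    flags_df = pd.DataFrame(
        flags,
        columns=["subject_id", "visit", "ds", "feature", "squared_distance", "p_value"],
    )
    if drop_keys:
        key = pd.MultiIndex.from_frame(
            cohort[["subject_id", "visit", "biomarker_id"]]
        )
        retained = cohort[~key.isin(drop_keys)].reset_index(drop=True)
    else:
        retained = cohort.reset_index(drop=True)
    report = report or QCReport()
    report.outlier_flags = flags_df
    report.retained_sizes["after_outliers"] = int(retained["subject_id"].nunique())
    return retained, report


def run_qc(
    cohort: pd.DataFrame,
    percentile: float = 10.0,
    alpha: float = 0.05,
    scope: str = "per-modality",
) -> tuple[pd.DataFrame, QCReport]:
    """The full fixed-order pipeline: converters -> likelihood -> outliers."""
    cohort, report = remove_converters(cohort)
    scores = diagnosis_likelihood_scores(cohort)
    cohort, report = filter_low_likelihood(cohort, scores, percentile, report=report)
    cohort, report = detect_outliers_mahalanobis(
        cohort, alpha=alpha, scope=scope, report=report
    )
    return cohort, report
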