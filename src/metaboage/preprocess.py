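"""Variable QC, multivariate outlier removal, between-cohort calibration,
k-NN imputation and VIF-based backward pruning."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .synthetic import ID_COLS, analyte_columns


class QCError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


class ImputationError(ValueError):
    pass


@dataclass
class QCReport:
    excluded_missing: list[str] = field(default_factory=list)
    excluded_replicate_corr: dict[str, float] = field(default_factory=dict)
    outlier_samples: dict[str, float] = field(default_factory=dict)
    retained_analytes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "excluded_missing": self.excluded_missing,
            "excluded_replicate_corr": self.excluded_replicate_corr,
            "outlier_samples": self.outlier_samples,
            "retained_analytes": self.retained_analytes,
        }


@dataclass
class CalibrationFactors:
    reference_cohort: str
    factors: pd.DataFrame           # cohort x analyte, reference row == 1
    matched_n: dict[str, int]       # cohort -> matched sample count
    method: str = "median"
    mode: str = "multiplicative"

    def to_dict(self) -> dict:
        return {
            "reference_cohort": self.reference_cohort,
            "method": self.method,
            "mode": self.mode,
            "matched_n": self.matched_n,
            "factors": {c: self.factors.loc[c].to_dict() for c in self.factors.index},
        }


@dataclass
class VifTrace:
    removal_order: list[tuple[str, float]]
    retained: list[str]
    threshold: float = 5.0

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "removal_order": [[a, v] for a, v in self.removal_order],
            "retained": self.retained,
        }


def filter_variables(
    matrix: pd.DataFrame,
    replicate_matrix: pd.DataFrame | None = None,
    missing_rule: float = 0.2,
    r_threshold: float = 0.7,
) -> QCReport:
    """Exclude analytes frequently missing in any cohort and analytes whose
    replicate-measurement Pearson correlation falls below ``r_threshold``.

    "Frequently missing" means a within-cohort missing fraction above
    ``missing_rule`` in at least one cohort.
    """
    analytes = analyte_columns(matrix)
    report = QCReport()
    miss = matrix.groupby("cohort")[analytes].apply(lambda g: g.isna().mean())
    for a in analytes:
        if (miss[a] > missing_rule).any():
            report.excluded_missing.append(a)

    if replicate_matrix is not None:
        shared = [
            a for a in analytes
            if a in replicate_matrix.columns and a not in report.excluded_missing
        ]
        rep = replicate_matrix.set_index("sample_id")
        main = matrix.set_index("sample_id")
        common = main.index.intersection(rep.index)
        for a in shared:
            x = main.loc[common, a].to_numpy(dtype=float)
            y = rep.loc[common, a].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                continue
            r = np.corrcoef(x[ok], y[ok])[0, 1]
            if not np.isfinite(r) or r < r_threshold:
                report.excluded_replicate_corr[a] = float(r)

    excluded = set(report.excluded_missing) | set(report.excluded_replicate_corr)
    report.retained_analytes = [a for a in analytes if a not in excluded]
    if not report.retained_analytes:
        raise QCError("variable QC excluded every analyte")
    return report


def _cohort_outlier_weights(X: np.ndarray, var_retained: float = 0.99) -> np.ndarray:
    """Outlier weights in [0, 1] for one cohort block.

    Median/MAD standardisation, PCA keeping ``var_retained`` of variance,
    component scores standardised by their MAD, squared score distance d2
    compared against a chi-square quantile c: weight 1 for d2 <= c, c/d2
    beyond.  Monotone non-increasing in d2; a compatible substitute for the
    reference robust-PCA weighting, not a replica.
    """
    med = np.median(X, axis=0)
    mad = stats.median_abs_deviation(X, axis=0, scale="normal")
    mad = np.where(mad > 0, mad, 1.0)
    Z = (X - med) / mad
    pca = PCA()
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_retained) + 1)
    k = min(k, scores.shape[1])
    s = scores[:, :k]
    s_mad = stats.median_abs_deviation(s, axis=0, scale="normal")
    s_mad = np.where(s_mad > 0, s_mad, 1.0)
    d2 = np.sum((s / s_mad) ** 2, axis=1)
    c = stats.chi2.ppf(0.975, df=k)
    w = np.where(d2 <= c, 1.0, (c / np.maximum(d2, 1e-300)) ** 2)
    return w


def detect_outliers(
    matrix: pd.DataFrame,
    per_cohort: bool = True,
    weight_threshold: float = 0.1,
) -> QCReport:
    """Flag multivariate location outliers (weight <= ``weight_threshold``).

    Weights are computed per cohort (or globally) on the complete-analyte
    submatrix.  Flagged samples should be dropped from downstream stages.
    """
    analytes = analyte_columns(matrix)
    report = QCReport(retained_analytes=list(analytes))
    groups = matrix.groupby("cohort") if per_cohort else [("all", matrix)]
    for cohort, g in groups:
        cols = [a for a in analytes if g[a].notna().all()]
        if not cols:
            continue
        if len(g) < 20:
            raise QCError(f"cohort {cohort} has fewer than 20 samples")
        X = g[cols].to_numpy(dtype=float)
        w = _cohort_outlier_weights(X)
        if len(g) - int((w <= weight_threshold).sum()) < len(cols):
            warnings.warn(
                f"cohort {cohort}: fewer samples than analytes after outlier removal"
            )
        for sid, wi in zip(g["sample_id"], w):
            if wi <= weight_threshold:
                report.outlier_samples[sid] = float(wi)
    return report


def drop_outliers(matrix: pd.DataFrame, report: QCReport) -> pd.DataFrame:
    return matrix[~matrix["sample_id"].isin(report.outlier_samples)].reset_index(drop=True)


def _strata(pheno: pd.DataFrame) -> pd.Series:
    """Matching strata: sex x 5-year age band x BMI class x ethnicity."""
    age_band = (pheno["age"] // 5).astype(int)
    bmi_class = pd.cut(
        pheno["bmi"], bins=[-np.inf, 25, 30, np.inf], labels=["lt25", "25to30", "ge30"]
    )
    return (
        pheno["sex"].astype(str)
        + "|" + age_band.astype(str)
        + "|" + bmi_class.astype(str)
        + "|" + pheno["ethnicity"].astype(str)
    )


def calibrate_cohorts(
    matrix: pd.DataFrame,
    pheno: pd.DataFrame,
    reference_cohort: str,
    method: str = "median",
    mode: str = "multiplicative",
) -> tuple[pd.DataFrame, CalibrationFactors]:
    """Estimate per-(cohort, analyte) scaling factors on demographically
    matched subsets and apply them to the full target cohorts.

    For each target cohort, samples falling in strata shared with the
    reference cohort are selected on both sides; the factor is
    location(reference matched) / location(target matched) and is applied
    multiplicatively to every target sample (reference left unchanged).
    ``mode='additive'`` uses a difference instead.
    """
    if reference_cohort not in set(matrix["cohort"]):
        raise CalibrationError(f"reference cohort {reference_cohort!r} not present")
    analytes = analyte_columns(matrix)
    loc = np.median if method == "median" else np.mean

    ph = pheno.set_index("sample_id")
    strata = _strata(ph)
    by_sample = matrix.set_index("sample_id")
    cohorts = list(dict.fromkeys(matrix["cohort"]))

    ref_ids = by_sample.index[by_sample["cohort"] == reference_cohort]
    ref_strata = strata.loc[ref_ids]

    factors = pd.DataFrame(
        1.0 if mode == "multiplicative" else 0.0, index=cohorts, columns=analytes
    )
    matched_n: dict[str, int] = {reference_cohort: int(len(ref_ids))}
    out = matrix.copy()

    for cohort in cohorts:
        if cohort == reference_cohort:
            continue
        tgt_ids = by_sample.index[by_sample["cohort"] == cohort]
        tgt_strata = strata.loc[tgt_ids]
        shared = set(ref_strata) & set(tgt_strata)
        if not shared:
            raise CalibrationError(f"no matched stratum between {cohort!r} and reference")
        ref_m = ref_ids[ref_strata.isin(shared)]
        tgt_m = tgt_ids[tgt_strata.isin(shared)]
        matched_n[cohort] = int(len(tgt_m))
        for a in analytes:
            rv = by_sample.loc[ref_m, a].to_numpy(dtype=float)
            tv = by_sample.loc[tgt_m, a].to_numpy(dtype=float)
            rv, tv = rv[np.isfinite(rv)], tv[np.isfinite(tv)]
            if len(rv) == 0 or len(tv) == 0:
                continue
            if mode == "multiplicative":
                denom = loc(tv)
                if denom == 0:
                    continue
                factors.loc[cohort, a] = loc(rv) / denom
            else:
                factors.loc[cohort, a] = loc(rv) - loc(tv)
        mask = out["cohort"] == cohort
        if mode == "multiplicative":
            out.loc[mask, analytes] = out.loc[mask, analytes].to_numpy() * factors.loc[cohort].to_numpy()[None, :]
        else:
            out.loc[mask, analytes] = out.loc[mask, analytes].to_numpy() + factors.loc[cohort].to_numpy()[None, :]

    if mode == "multiplicative" and not (factors.to_numpy() > 0).all():
        raise CalibrationError("non-positive calibration factor estimated")
    cf = CalibrationFactors(reference_cohort, factors, matched_n, method, mode)
    return out, cf


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing analyte entries by the mean of the k nearest samples.

    Distances are Euclidean in the z-scored space of analytes observed for
    every sample; neighbours are restricted to samples where the target
    analyte is observed.  Observed entries are untouched.
    """
    analytes = analyte_columns(matrix)
    vals = matrix[analytes].to_numpy(dtype=float)
    if not np.isnan(vals).any():
        return matrix.copy()
    obs_any = np.isfinite(vals).any(axis=1)
    if not obs_any.all():
        raise ImputationError("some samples have no observed analytes")
    complete = [i for i, a in enumerate(analytes) if np.isfinite(vals[:, i]).all()]
    if not complete:
        raise ImputationError("no fully observed analytes to define neighbour space")

    C = vals[:, complete]
    mu, sd = C.mean(axis=0), C.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (C - mu) / sd

    out = vals.copy()
    for j, a in enumerate(analytes):
        col = vals[:, j]
        missing = np.where(~np.isfinite(col))[0]
        if len(missing) == 0:
            continue
        donors = np.where(np.isfinite(col))[0]
        if len(donors) == 0:
            raise ImputationError(f"analyte {a} missing in all samples")
        kk = min(k, len(donors))
        nn = NearestNeighbors(n_neighbors=kk).fit(Z[donors])
        _, idx = nn.kneighbors(Z[missing])
        out[missing, j] = col[donors[idx]].mean(axis=1)

    res = matrix.copy()
    res[analytes] = out
    return res


def _vif_all(R: np.ndarray) -> np.ndarray:
    """VIFs from a correlation matrix; singular matrices yield +inf."""
    p = R.shape[0]
    try:
        Rinv = np.linalg.inv(R)
        vif = np.diag(Rinv).copy()
        if np.all(vif > 1.0 - 1e-8) and np.isfinite(vif).all():
            return np.maximum(vif, 1.0)
        raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vif = np.empty(p)
        for j in range(p):
            others = [i for i in range(p) if i != j]
            r = R[np.ix_(others, others)]
            c = R[others, j]
            r2 = float(c @ np.linalg.lstsq(r, c, rcond=None)[0])
            vif[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return vif


def vif_prune(matrix: pd.DataFrame, threshold: float = 5.0) -> VifTrace:
    """Backward stepwise removal of the max-VIF analyte until all VIF < threshold.

    VIF_j = 1/(1 - R2_j) with R2_j from regressing analyte j on the
    remaining analytes (computed via the inverse correlation matrix).
    Ties on the maximum are broken by column order.  Perfectly collinear
    variables surface as VIF = +inf and are removed first.
    """
    analytes = [a for a in analyte_columns(matrix) if matrix[a].notna().all()]
    if len(analytes) < 2:
        raise QCError("need at least 2 fully observed analytes for VIF pruning")
    X = matrix[analytes].to_numpy(dtype=float)
    if X.shape[0] <= len(analytes):
        warnings.warn("fewer samples than analytes; VIFs may be unstable")
    R_full = np.corrcoef(X, rowvar=False)

    active = list(range(len(analytes)))
    removal_order: list[tuple[str, float]] = []
    while len(active) >= 2:
        R = R_full[np.ix_(active, active)]
        vifs = _vif_all(R)
        jmax = int(np.argmax(vifs))  # argmax takes first occurrence: column-order ties
        if vifs[jmax] < threshold:
            break
        removal_order.append((analytes[active[jmax]], float(vifs[jmax])))
        active.pop(jmax)
    retained = [analytes[i] for i in active]
    return VifTrace(removal_order=removal_order, retained=retained, threshold=threshold)
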