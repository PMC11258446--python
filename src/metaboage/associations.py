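"""Chronological-age-adjusted association analyses of metabolomic age
scores with binary risk factors, continuous aging biomarkers, and incident
events, pooled across cohorts by fixed-effect IVW meta-analysis.

Conventions: linear-model estimates are in score-SD units (per exposure
contrast, or per biomarker SD); Cox estimates are hazard ratios per year
of metabolomic age.  Statistical significance is flagged at p < 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .mwas import CohortEffect, meta_fixed_one

P_REPORT = 0.001


class AssociationError(ValueError):
    pass


@dataclass
class AssocResult:
    score_name: str
    target: str
    model: str          # 'linear' | 'cox'
    estimate: float     # linear: SD score; cox: HR per score-year
    se: float
    ci95: tuple[float, float]
    p: float
    k: int
    stratum: str | None = None

    @property
    def significant(self) -> bool:
        return self.p < P_REPORT

    def to_row(self) -> dict:
        return {
            "score": self.score_name,
            "exposure": self.target,
            "model": self.model,
            "estimate": self.estimate,
            "lcl": self.ci95[0],
            "ucl": self.ci95[1],
            "se": self.se,
            "p": self.p,
            "k": self.k,
            "stratum": self.stratum or "",
            "sig_at_0.001": self.significant,
        }


def _covar_design(ph: pd.DataFrame, covars: list[str]) -> np.ndarray:
    cols = [np.ones(len(ph))]
    for c in covars:
        if ph[c].dtype == object or c == "ethnicity":
            for lev in sorted(ph[c].astype(str).unique())[1:]:
                cols.append((ph[c].astype(str) == lev).to_numpy(dtype=float))
        else:
            cols.append(ph[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _ols_effect(y: np.ndarray, x: np.ndarray, C: np.ndarray):
    """Coefficient and SE of x in OLS of y on [C, x]."""
    X = np.column_stack([C, x])
    XtX_inv = np.linalg.pinv(X.T @ X)
    b = XtX_inv @ (X.T @ y)
    resid = y - X @ b
    dof = len(y) - np.linalg.matrix_rank(X)
    if dof <= 0:
        return np.nan, np.nan
    s2 = resid @ resid / dof
    se = np.sqrt(s2 * XtX_inv[-1, -1])
    return float(b[-1]), float(se)


def _drop_repeat_visits(df: pd.DataFrame, repeat_visits: tuple[int, ...] = (2,)) -> pd.DataFrame:
    if "visit" in df.columns:
        return df[~df["visit"].isin(repeat_visits)]
    return df


def _pool(effects: list[CohortEffect], score_name: str, target: str,
          model: str, exp_scale: bool, stratum: str | None = None) -> AssocResult:
    d = meta_fixed_one([e.beta for e in effects], [e.se for e in effects])
    b, se = d["beta_pooled"], d["se_pooled"]
    lo, hi = b - 1.96 * se, b + 1.96 * se
    if exp_scale:
        est, lo, hi = float(np.exp(b)), float(np.exp(lo)), float(np.exp(hi))
    else:
        est = b
    return AssocResult(
        score_name=score_name, target=target, model=model,
        estimate=est, se=se, ci95=(lo, hi), p=d["p"], k=d["k"], stratum=stratum,
    )


def riskfactor_assoc(
    scores: np.ndarray,
    pheno: pd.DataFrame,
    factor: str,
    covars: list[str] = ("age", "sex", "ethnicity"),
    score_name: str = "score",
    exclude_repeat_visits: bool = True,
) -> AssocResult:
    """Per-cohort linear regression of the SD-standardized score on a binary
    risk factor + covariates, IVW-pooled.  Cohorts where the factor is
    constant are skipped with a warning."""
    df = pheno.copy()
    df["_score"] = np.asarray(scores, dtype=float)
    if exclude_repeat_visits:
        df = _drop_repeat_visits(df)
    sd = df["_score"].std()
    if sd == 0:
        raise AssociationError("constant score")
    df["_score"] = (df["_score"] - df["_score"].mean()) / sd

    effects = []
    for cohort, g in df.groupby("cohort", sort=False):
        x = g[factor].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"risk factor {factor!r} constant in cohort {cohort}; skipped")
            continue
        ok = np.isfinite(x)
        C = _covar_design(g[ok], list(covars))
        b, se = _ols_effect(g.loc[ok, "_score"].to_numpy(), x[ok], C)
        if np.isfinite(b) and np.isfinite(se) and se > 0:
            effects.append(CohortEffect(factor, str(cohort), b, se, int(ok.sum())))
    if not effects:
        raise AssociationError(f"no usable cohorts for factor {factor!r}")
    return _pool(effects, score_name, factor, "linear", exp_scale=False)


def biomarker_assoc(
    scores: np.ndarray,
    pheno: pd.DataFrame,
    biomarker: str,
    covars: list[str] = ("age", "sex", "ethnicity"),
    score_name: str = "score",
    exclude_repeat_visits: bool = True,
) -> AssocResult:
    """SD score per SD of a continuous biomarker (univariate z-scaled within
    the analysis sample), CA/sex/ethnicity-adjusted, IVW-pooled."""
    df = pheno.copy()
    df["_score"] = np.asarray(scores, dtype=float)
    if exclude_repeat_visits:
        df = _drop_repeat_visits(df)
    df = df[np.isfinite(df[biomarker].to_numpy(dtype=float))]
    if df.empty:
        raise AssociationError(f"biomarker {biomarker!r} entirely missing")
    for col in ("_score", biomarker):
        sd = df[col].std()
        if sd == 0:
            raise AssociationError(f"{col} constant in analysis sample")
        df[col] = (df[col] - df[col].mean()) / sd

    effects = []
    for cohort, g in df.groupby("cohort", sort=False):
        if g[biomarker].std() == 0:
            warnings.warn(f"biomarker {biomarker!r} constant in cohort {cohort}; skipped")
            continue
        C = _covar_design(g, list(covars))
        b, se = _ols_effect(g["_score"].to_numpy(), g[biomarker].to_numpy(), C)
        if np.isfinite(b) and np.isfinite(se) and se > 0:
            effects.append(CohortEffect(biomarker, str(cohort), b, se, len(g)))
    if not effects:
        raise AssociationError(f"no usable cohorts for biomarker {biomarker!r}")
    return _pool(effects, score_name, biomarker, "linear", exp_scale=False)


def cox_event_assoc(
    scores: np.ndarray,
    pheno: pd.DataFrame,
    covars: list[str] = ("age", "sex", "ethnicity"),
    score_name: str = "score",
    event_name: str = "event",
    age_bands: list[tuple[float, float]] | None = None,
) -> list[AssocResult]:
    """CA-adjusted Cox models of incident events on the score (year units);
    HR per year of metabolomic age, IVW-pooled on the log scale.

    With ``age_bands`` (e.g. [(0,55),(55,65),(65,inf)]) one pooled result is
    returned per band; otherwise a single-element list.
    """
    df = pheno.copy()
    df["_score"] = np.asarray(scores, dtype=float)
    df = df[np.isfinite(df["surv_time"]) & np.isfinite(df["event"])]
    if df["event"].sum() == 0:
        raise AssociationError("zero events")
    bands = age_bands or [(-np.inf, np.inf)]
    results = []
    for lo, hi in bands:
        stratum = None if age_bands is None else f"{lo:g}-{hi:g}"
        sub = df[(df["age"] >= lo) & (df["age"] < hi)]
        effects = []
        for cohort, g in sub.groupby("cohort", sort=False):
            if g["event"].sum() == 0 or len(g) < 10:
                continue
            cols = {"_score": g["_score"].to_numpy(),
                    "surv_time": g["surv_time"].to_numpy(),
                    "event": g["event"].to_numpy()}
            for c in covars:
                if g[c].dtype == object or c == "ethnicity":
                    for lev in sorted(g[c].astype(str).unique())[1:]:
                        cols[f"{c}_{lev}"] = (g[c].astype(str) == lev).to_numpy(dtype=float)
                else:
                    if g[c].std() == 0:
                        continue
                    cols[c] = g[c].to_numpy(dtype=float)
            cdf = pd.DataFrame(cols)
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(cdf, duration_col="surv_time", event_col="event")
            except Exception as exc:
                warnings.warn(f"Cox fit failed in cohort {cohort}: {exc}")
                continue
            b = float(cph.params_["_score"])
            se = float(cph.standard_errors_["_score"])
            if np.isfinite(b) and np.isfinite(se) and se > 0:
                effects.append(CohortEffect(event_name, str(cohort), b, se, len(g)))
        if effects:
            results.append(_pool(effects, score_name, event_name, "cox",
                                 exp_scale=True, stratum=stratum))
    if not results:
        raise AssociationError("no cohort produced a usable Cox estimate")
    return results


def sensitivity_adjust(analysis, *args, extra_covars: tuple[str, ...] = ("bmi",),
                       covars: list[str] = ("age", "sex", "ethnicity"), **kwargs):
    """Re-run an association analysis with extra covariates (default +BMI);
    output schema identical to the unadjusted run."""
    full = list(covars) + [c for c in extra_covars if c not in covars]
    return analysis(*args, covars=full, **kwargs)


def assoc_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def wald_ci_covers(estimate: float, se: float, value: float, log_scale: bool = False) -> bool:
    """Utility for coverage checks in simulations."""
    b = np.log(estimate) if log_scale else estimate
    v = np.log(value) if log_scale else value
    return (b - 1.96 * se) <= v <= (b + 1.96 * se)

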