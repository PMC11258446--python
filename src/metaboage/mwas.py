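"""Metabolome-wide association studies of age and mortality, pooled by
inverse-variance fixed-effect meta-analysis with Cochran's Q / I2 and
Benjamini-Hochberg FDR."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .synthetic import analyte_columns

DEFAULT_AGE_BINS = [(20, 35), (35, 40), (40, 45), (45, 50), (50, 55),
                    (55, 60), (60, 65), (65, 70), (70, np.inf)]


@dataclass
class CohortEffect:
    analyte: str
    cohort: str
    beta: float
    se: float
    n: int

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise ValueError(f"non-finite effect for {self.analyte}/{self.cohort}")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValueError(f"invalid SE for {self.analyte}/{self.cohort}")


@dataclass
class MetaResult:
    analyte: str
    beta_pooled: float
    se_pooled: float
    z: float
    p: float
    Q_stat: float
    df: int
    I2: float
    k: int
    q: float = np.nan

    @property
    def het_label(self) -> str:
        if self.I2 > 0.75:
            return "high"
        if self.I2 < 0.25:
            return "low"
        return "moderate"


def _design(ph: pd.DataFrame, covars: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; categorical ethnicity dummy-coded and
    dropped automatically when single-level."""
    cols = [np.ones(len(ph))]
    names = ["const"]
    for c in covars:
        if c == "ethnicity" or ph[c].dtype == object:
            levels = sorted(ph[c].astype(str).unique())
            for lev in levels[1:]:
                cols.append((ph[c].astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
        else:
            cols.append(ph[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def _multi_ols(X: np.ndarray, Y: np.ndarray, j_target: int) -> tuple[np.ndarray, np.ndarray]:
    """OLS of each column of Y on X; return (beta, se) of predictor ``j_target``."""
    n, q = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    B = XtX_inv @ (X.T @ Y)
    resid = Y - X @ B
    dof = n - q
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[j_target, j_target])
    return B[j_target], se


def _zscale(v: np.ndarray) -> np.ndarray:
    sd = np.nanstd(v, axis=0)
    sd = np.where(sd > 0, sd, np.nan)
    return (v - np.nanmean(v, axis=0)) / sd


def mwas_age(
    matrix: pd.DataFrame,
    pheno: pd.DataFrame,
    covars: list[str] = ("sex", "bmi", "ethnicity"),
) -> list[CohortEffect]:
    """Cohort-stratified linear MWAS of age: per (analyte, cohort),
    z-scored analyte ~ age + sex + BMI + ethnicity; returns the age
    coefficient (SD per year) and its SE."""
    analytes = analyte_columns(matrix)
    merged = matrix.merge(pheno[["sample_id", "age"] + [c for c in covars]],
                          on="sample_id")
    effects: list[CohortEffect] = []
    for cohort, g in merged.groupby("cohort", sort=False):
        X, names = _design(g, ["age"] + list(covars))
        j_age = names.index("age")
        Y = g[analytes].to_numpy(dtype=float)
        present = [a for i, a in enumerate(analytes) if np.isfinite(Y[:, i]).all()]
        idx = [analytes.index(a) for a in present]
        Z = _zscale(Y[:, idx])
        const = np.nanstd(Y[:, idx], axis=0) == 0
        if const.any():
            warnings.warn(f"constant analytes skipped in cohort {cohort}")
        keep = ~const
        beta, se = _multi_ols(X, Z[:, keep], j_age)
        for a, b, s in zip(np.array(present)[keep], beta, se):
            if np.isfinite(b) and np.isfinite(s) and s > 0:
                effects.append(CohortEffect(a, str(cohort), float(b), float(s), len(g)))
    return effects


def mwas_age_stratified(
    matrix: pd.DataFrame,
    pheno: pd.DataFrame,
    bins: list[tuple[float, float]] | None = None,
    covars: list[str] = ("sex", "bmi", "ethnicity"),
    min_n: int = 30,
) -> list[CohortEffect]:
    """Age-group-stratified MWAS (strata act as studies), additionally
    adjusted for cohort.  Default bins: 20-35, 35-40, ..., 65-70, >70."""
    bins = list(bins) if bins is not None else list(DEFAULT_AGE_BINS)
    for (a0, a1), (b0, b1) in zip(bins, bins[1:]):
        if b0 < a1:
            raise ValueError("age bins must be ordered and non-overlapping")
    analytes = analyte_columns(matrix)
    merged = matrix.merge(pheno[["sample_id", "age"] + [c for c in covars]],
                          on="sample_id")
    effects: list[CohortEffect] = []
    for lo, hi in bins:
        g = merged[(merged["age"] >= lo) & (merged["age"] < hi)]
        label = f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}"
        if len(g) < min_n:
            warnings.warn(f"age stratum {label} has n={len(g)} < {min_n}; skipped")
            continue
        strat_covars = list(covars)
        if g["cohort"].nunique() > 1:
            strat_covars.append("cohort")
        X, names = _design(g, ["age"] + strat_covars)
        j_age = names.index("age")
        Y = g[analytes].to_numpy(dtype=float)
        present_idx = [i for i in range(len(analytes)) if np.isfinite(Y[:, i]).all()
                       and np.nanstd(Y[:, i]) > 0]
        Z = _zscale(Y[:, present_idx])
        beta, se = _multi_ols(X, Z, j_age)
        for i, b, s in zip(present_idx, beta, se):
            if np.isfinite(b) and np.isfinite(s) and s > 0:
                effects.append(CohortEffect(analytes[i], label, float(b), float(s), len(g)))
    return effects


def mwas_mortality(
    matrix: pd.DataFrame,
    pheno: pd.DataFrame,
    covars: list[str] = ("age", "sex", "bmi"),
) -> list[CohortEffect]:
    """Per-(analyte, cohort) Cox models: hazard ~ analyte + age + sex + BMI.

    Returns log hazard ratios per analyte-SD.  Cohorts without survival
    data or without events are skipped.  Breslow tie handling.
    """
    analytes = analyte_columns(matrix)
    merged = matrix.merge(
        pheno[["sample_id", "surv_time", "event"] + list(covars)], on="sample_id"
    )
    merged = merged[np.isfinite(merged["surv_time"]) & np.isfinite(merged["event"])]
    effects: list[CohortEffect] = []
    for cohort, g in merged.groupby("cohort", sort=False):
        if g["event"].sum() == 0:
            warnings.warn(f"cohort {cohort} has zero events; skipped")
            continue
        base = g[list(covars)].copy()
        for a in analytes:
            v = g[a].to_numpy(dtype=float)
            if not np.isfinite(v).all() or np.nanstd(v) == 0:
                continue
            df = base.copy()
            df["x"] = (v - v.mean()) / v.std()
            df["surv_time"] = g["surv_time"].to_numpy()
            df["event"] = g["event"].to_numpy()
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df, duration_col="surv_time", event_col="event")
            except Exception as exc:  # convergence failure on one analyte
                warnings.warn(f"Cox fit failed for {a}/{cohort}: {exc}")
                continue
            b = float(cph.params_["x"])
            s = float(cph.standard_errors_["x"])
            if np.isfinite(b) and np.isfinite(s) and s > 0:
                effects.append(CohortEffect(a, str(cohort), b, s, len(g)))
    return effects


def meta_fixed_one(betas: np.ndarray, ses: np.ndarray) -> dict:
    """IVW fixed-effect pooling of one analyte's per-study effects."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if np.any(ses <= 0) or not np.all(np.isfinite(ses)):
        raise ValueError("all standard errors must be positive and finite")
    w = ses ** -2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    Q = float(np.sum(w * (betas - beta) ** 2))
    df = len(betas) - 1
    I2 = float(max(0.0, (Q - df) / Q)) if Q > 0 else 0.0
    return {"beta_pooled": beta, "se_pooled": se, "z": float(z), "p": p,
            "Q_stat": Q, "df": df, "I2": I2, "k": len(betas)}


def meta_fixed(effects: list[CohortEffect]) -> list[MetaResult]:
    """Pool per-study effects analyte by analyte and attach BH-FDR q-values."""
    by_analyte: dict[str, list[CohortEffect]] = {}
    for e in effects:
        by_analyte.setdefault(e.analyte, []).append(e)
    results = []
    for analyte, es in by_analyte.items():
        d = meta_fixed_one([e.beta for e in es], [e.se for e in es])
        results.append(MetaResult(analyte=analyte, **d))
    qs = bh_fdr(np.array([r.p for r in results]))
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN p-values propagate as NaN (with a warning) and do not count toward m.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    nan = np.isnan(p)
    if nan.any():
        warnings.warn("NaN p-values propagated through BH adjustment")
    pv = p[~nan]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[~nan] = res
    return out


def meta_to_frame(results: list[MetaResult]) -> pd.DataFrame:
    """Tidy CSV-ready view of meta-analysis results."""
    return pd.DataFrame(
        {
            "analyte": [r.analyte for r in results],
            "k": [r.k for r in results],
            "beta": [r.beta_pooled for r in results],
            "se": [r.se_pooled for r in results],
            "z": [r.z for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "Q": [r.Q_stat for r in results],
            "df": [r.df for r in results],
            "I2": [r.I2 for r in results],
            "het_label": [r.het_label for r in results],
        }
    )
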