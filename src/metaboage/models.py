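"""The four study aging models and published coefficient-table scores.

* elastic net on chronological age (alpha 0.5, CV-chosen lambda)
* degree-2 MARS on chronological age
* phenotypic age: elastic net on age with mortality-p-value penalty factors
  (opposing age/mortality directions force a penalty factor of 1)
* mortality score: elastic-net-penalized Cox on survival, analyte terms
  only, rescaled to age units
* external scores from coefficient tables (weight + transform + scaling)
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import enet
from . import mars as mars_engine
from .mwas import MetaResult
from .preprocess import knn_impute
from .synthetic import analyte_columns

KINDS = {"elastic_net", "mars", "phenotypic", "mortality_score", "external"}


class ModelError(ValueError):
    pass


@dataclass
class AgingModel:
    kind: str
    analytes: list[str]
    intercept: float = 0.0
    coefficients: np.ndarray | None = None
    mars_model: mars_engine.MarsModel | None = None
    penalty_factors: np.ndarray | None = None
    rescale: tuple[float, float, float, float] | None = None  # score m/sd, age m/sd
    standardize: tuple[np.ndarray, np.ndarray] | None = None  # analyte mean/sd
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ModelError(f"unknown model kind {self.kind!r}")
        if (self.penalty_factors is not None) != (self.kind == "phenotypic"):
            raise ModelError("penalty_factors present iff kind='phenotypic'")

    def to_json(self) -> str:
        def arr(a):
            return None if a is None else [float(x) for x in np.asarray(a).ravel()]

        return json.dumps(
            {
                "schema": "metaboage.aging_model/1",
                "kind": self.kind,
                "analytes": self.analytes,
                "intercept": self.intercept,
                "coefficients": arr(self.coefficients),
                "mars_model": (
                    None if self.mars_model is None else json.loads(self.mars_model.to_json())
                ),
                "penalty_factors": arr(self.penalty_factors),
                "rescale": None if self.rescale is None else list(self.rescale),
                "standardize": (
                    None
                    if self.standardize is None
                    else [arr(self.standardize[0]), arr(self.standardize[1])]
                ),
                "meta": self.meta,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, s: str) -> "AgingModel":
        d = json.loads(s)

        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        return cls(
            kind=d["kind"],
            analytes=list(d["analytes"]),
            intercept=float(d["intercept"]),
            coefficients=arr(d["coefficients"]),
            mars_model=(
                None
                if d["mars_model"] is None
                else mars_engine.MarsModel.from_json(json.dumps(d["mars_model"]))
            ),
            penalty_factors=arr(d["penalty_factors"]),
            rescale=None if d["rescale"] is None else tuple(d["rescale"]),
            standardize=(
                None
                if d["standardize"] is None
                else (arr(d["standardize"][0]), arr(d["standardize"][1]))
            ),
            meta=d.get("meta", {}),
        )


def rescale_to_age_units(scores: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Affine-map scores to the mean/SD of chronological age (year units)."""
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    sd = scores.std()
    if sd == 0:
        raise ModelError("cannot rescale constant scores to age units")
    return (scores - scores.mean()) / sd * ages.std() + ages.mean()


def fit_elastic_net_age(
    X: pd.DataFrame,
    age: np.ndarray,
    alpha: float = 0.5,
    penalty_factors: np.ndarray | None = None,
    seed: int = 0,
    n_folds: int = 10,
    rule: str = "min",
    kind: str = "elastic_net",
) -> AgingModel:
    """Elastic net of age on the pruned analyte set; lambda by K-fold CV."""
    analytes = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    age = np.asarray(age, dtype=float)
    if np.all(Xv.std(axis=0) == 0):
        raise ModelError("all predictors are constant")
    path, i_opt = enet.cv_fit(
        Xv, age, alpha=alpha, penalty_factors=penalty_factors,
        n_folds=n_folds, seed=seed, rule=rule,
    )
    return AgingModel(
        kind=kind,
        analytes=analytes,
        intercept=float(path.intercepts[i_opt]),
        coefficients=path.coefs[i_opt].copy(),
        penalty_factors=(
            None if kind != "phenotypic" else np.asarray(penalty_factors, dtype=float)
        ),
        meta={"alpha": alpha, "lambda": float(path.lambdas[i_opt]), "seed": seed,
              "cv_rule": rule},
    )


def mortality_penalty_factors(
    age_meta: list[MetaResult],
    mort_meta: list[MetaResult],
    analytes: list[str],
) -> np.ndarray:
    """Penalty multipliers: the analyte's pooled mortality p-value, forced to
    1 when its age and mortality effects point in opposite directions."""
    age_by = {r.analyte: r for r in age_meta}
    mort_by = {r.analyte: r for r in mort_meta}
    v = np.empty(len(analytes))
    for i, a in enumerate(analytes):
        if a not in age_by:
            raise ModelError(f"analyte {a!r} missing from age meta-analysis")
        if a not in mort_by:
            raise ModelError(f"analyte {a!r} missing from mortality meta-analysis")
        if np.sign(age_by[a].beta_pooled) != np.sign(mort_by[a].beta_pooled):
            v[i] = 1.0
        else:
            v[i] = min(1.0, max(0.0, mort_by[a].p))
    return v


def fit_phenotypic_age(
    X: pd.DataFrame,
    age: np.ndarray,
    penalty_factors: np.ndarray,
    alpha: float = 0.5,
    seed: int = 0,
    n_folds: int = 10,
) -> AgingModel:
    return fit_elastic_net_age(
        X, age, alpha=alpha, penalty_factors=penalty_factors, seed=seed,
        n_folds=n_folds, kind="phenotypic",
    )


def fit_mars_age(
    X: pd.DataFrame,
    age: np.ndarray,
    max_terms: int = 21,
    max_knots_per_var: int = 31,
    seed: int = 0,
) -> AgingModel:
    fwd = mars_engine.forward_pass(
        X.to_numpy(dtype=float), np.asarray(age, dtype=float),
        max_terms=max_terms, max_knots_per_var=max_knots_per_var,
    )
    if len(fwd.terms) > 1:
        pruned = mars_engine.backward_prune(fwd, X.to_numpy(dtype=float),
                                            np.asarray(age, dtype=float))
    else:
        pruned = fwd
    return AgingModel(
        kind="mars", analytes=list(X.columns), mars_model=pruned,
        meta={"max_terms": max_terms, "max_knots_per_var": max_knots_per_var,
              "seed": seed},
    )


def fit_mortality_score(
    X: pd.DataFrame,
    covariates: pd.DataFrame,
    surv_time: np.ndarray,
    event: np.ndarray,
    alpha: float = 0.5,
    ages: np.ndarray | None = None,
    seed: int = 0,
    n_folds: int = 5,
) -> AgingModel:
    """Elastic-net-penalized Cox on analytes + covariates (alpha 0.5).

    Covariates get penalty factor 0 (always retained); the score keeps only
    the analyte terms of the linear predictor and is rescaled to the
    mean/SD of training chronological age.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.metrics import concordance_index_censored
    from sksurv.util import Surv

    event = np.asarray(event, dtype=bool)
    surv_time = np.asarray(surv_time, dtype=float)
    if event.sum() == 0:
        raise ModelError("no events in training data")
    analytes = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    mu, sd = Xa.mean(axis=0), Xa.std(axis=0)
    if np.any(sd == 0):
        raise ModelError("constant analyte column")
    Z = (Xa - mu) / sd

    cov_num = pd.get_dummies(covariates, drop_first=True).astype(float)
    cov_cols = list(cov_num.columns)
    D = np.column_stack([Z, cov_num.to_numpy()])
    pf = np.concatenate([np.ones(len(analytes)), np.zeros(len(cov_cols))])
    y = Surv.from_arrays(event=event, time=surv_time)

    base = CoxnetSurvivalAnalysis(l1_ratio=alpha, penalty_factor=pf, n_alphas=40)
    base.fit(D, y)
    alphas = base.alphas_

    rng = np.random.default_rng(seed)
    folds = rng.permutation(len(surv_time)) % n_folds
    scores = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        if event[te].sum() == 0 or event[tr].sum() == 0:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=alpha, penalty_factor=pf, alphas=alphas)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(D[tr], y[tr])
        for i, a in enumerate(m.alphas_):
            lp = m.predict(D[te], alpha=a)
            if np.std(lp) == 0:
                continue
            ci = concordance_index_censored(event[te], surv_time[te], lp)[0]
            j = int(np.argmin(np.abs(alphas - a)))
            scores[j] += ci
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        mean_ci = np.where(counts > 0, scores / np.maximum(counts, 1), -np.inf)
    i_opt = int(np.argmax(mean_ci)) if np.isfinite(mean_ci).any() else len(alphas) // 2

    coef_all = base.coef_[:, i_opt]
    beta_z = coef_all[: len(analytes)]
    # back to original concentration scale
    beta = beta_z / sd
    intercept = -float(mu @ beta)

    raw = Xa @ beta + intercept
    if ages is None:
        ages = covariates["age"].to_numpy(dtype=float)
    if raw.std() == 0:
        raise ModelError("degenerate mortality score (all-zero analyte terms)")
    rescale = (float(raw.mean()), float(raw.std()), float(np.mean(ages)), float(np.std(ages)))
    return AgingModel(
        kind="mortality_score",
        analytes=analytes,
        intercept=intercept,
        coefficients=beta,
        rescale=rescale,
        meta={"alpha": alpha, "lambda": float(alphas[i_opt]), "seed": seed,
              "n_events": int(event.sum())},
    )


@dataclass
class CoefficientTable:
    """Published-score specification: per-analyte weight + transform."""

    analytes: list[str]
    weights: np.ndarray
    transforms: list[str]       # 'none' | 'log'
    scalings: list[str]         # 'none' | 'cohort_z'
    rescale_rule: str = "none"  # 'none' | 'to_age_units'

    def __post_init__(self):
        if len(set(self.analytes)) != len(self.analytes):
            raise ModelError("duplicate analyte names in coefficient table")
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ModelError("coefficient weights must be finite")

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write(f"# rescale_rule: {self.rescale_rule}\n")
        pd.DataFrame(
            {
                "analyte": self.analytes,
                "weight": self.weights,
                "transform": self.transforms,
                "scaling": self.scalings,
            }
        ).to_csv(buf, index=False)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "CoefficientTable":
        rescale_rule = "none"
        lines = []
        for line in text.splitlines():
            if line.startswith("#"):
                if "rescale_rule:" in line:
                    rescale_rule = line.split("rescale_rule:")[1].strip()
            else:
                lines.append(line)
        df = pd.read_csv(io.StringIO("\n".join(lines)))
        required = {"analyte", "weight", "transform", "scaling"}
        if not required.issubset(df.columns):
            raise ModelError(f"coefficient table must have columns {sorted(required)}")
        return cls(
            analytes=df["analyte"].tolist(),
            weights=df["weight"].to_numpy(dtype=float),
            transforms=df["transform"].tolist(),
            scalings=df["scaling"].tolist(),
            rescale_rule=rescale_rule,
        )


def deelen_style_template(analytes: list[str]) -> CoefficientTable:
    """14-analyte weighted-sum schema: log transform + per-cohort z-scaling,
    rescaled to age units (weights must be supplied from the source score)."""
    chosen = analytes[:14]
    return CoefficientTable(
        analytes=chosen,
        weights=np.zeros(len(chosen)),
        transforms=["log"] * len(chosen),
        scalings=["cohort_z"] * len(chosen),
        rescale_rule="to_age_units",
    )


def apply_coefficient_table(
    matrix: pd.DataFrame,
    pheno: pd.DataFrame,
    table: CoefficientTable,
    impute_missing: bool = True,
    knn_k: int = 10,
) -> np.ndarray:
    """Per-sample weighted sum of transformed analytes.

    Analytes missing in some cohorts are k-NN imputed first (if enabled);
    analytes absent from the matrix entirely raise an error listing them.
    """
    absent = [a for a in table.analytes if a not in matrix.columns
              or matrix[a].isna().all()]
    if absent:
        raise ModelError(f"analytes unavailable for scoring: {absent}")
    work = matrix
    needs_impute = any(matrix[a].isna().any() for a in table.analytes)
    if needs_impute:
        if not impute_missing:
            missing = [a for a in table.analytes if matrix[a].isna().any()]
            raise ModelError(f"missing values in analytes {missing} and imputation disabled")
        work = knn_impute(matrix, k=knn_k)

    score = np.zeros(len(work))
    cohorts = work["cohort"].to_numpy()
    for a, w, tr, sc in zip(table.analytes, table.weights, table.transforms,
                            table.scalings):
        x = work[a].to_numpy(dtype=float)
        if tr == "log":
            x = np.log(np.maximum(x, 1e-12))
        elif tr != "none":
            raise ModelError(f"unknown transform {tr!r}")
        if sc == "cohort_z":
            for c in pd.unique(cohorts):
                m = cohorts == c
                sd = x[m].std()
                x[m] = (x[m] - x[m].mean()) / (sd if sd > 0 else 1.0)
        elif sc != "none":
            raise ModelError(f"unknown scaling {sc!r}")
        score = score + w * x

    if table.rescale_rule == "to_age_units":
        ages = pheno.set_index("sample_id").loc[work["sample_id"], "age"].to_numpy()
        score = rescale_to_age_units(score, ages)
    elif table.rescale_rule != "none":
        raise ModelError(f"unknown rescale_rule {table.rescale_rule!r}")
    return score


def predict_age(model: AgingModel, matrix: pd.DataFrame) -> np.ndarray:
    """Score a MetaboliteMatrix with a fitted aging model (deterministic)."""
    missing = [a for a in model.analytes if a not in matrix.columns]
    if missing:
        raise ModelError(f"matrix lacks analytes required by model: {missing}")
    X = matrix[model.analytes].to_numpy(dtype=float)
    if model.kind == "mars":
        raw = model.mars_model.predict(X)
    elif model.kind in {"elastic_net", "phenotypic", "mortality_score", "external"}:
        raw = X @ model.coefficients + model.intercept
    else:  # pragma: no cover
        raise ModelError(f"cannot score kind {model.kind!r}")
    if model.rescale is not None:
        s_m, s_sd, a_m, a_sd = model.rescale
        raw = (raw - s_m) / s_sd * a_sd + a_m
    return raw
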