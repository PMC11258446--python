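"""Model assessment: 7-fold cross-validation (subject-level folds),
leave-one-cohort-out validation, and longitudinal delta-age concordance.

A *trainer* is any callable ``trainer(X, y) -> predict_fn`` where
``predict_fn(X) -> y_hat``; the CV drivers are agnostic to the model
family behind it.

Pooled correlation/MAE are computed from the pooled out-of-fold
predictions (one r over all held-out samples), not by averaging per-fold
statistics; per-fold values are also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class EvaluationError(ValueError):
    pass


@dataclass
class CvReport:
    scheme: str                       # 'kfold' | 'loco'
    fold_r: dict[str, float]
    fold_mae: dict[str, float]
    pooled_r: float
    pooled_mae: float
    fold_assignment: dict[str, str]   # subject_id -> fold label
    seed: int | None = None
    predictions: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "fold_r": self.fold_r,
            "fold_mae": self.fold_mae,
            "pooled_r": self.pooled_r,
            "pooled_mae": self.pooled_mae,
            "seed": self.seed,
        }


@dataclass
class DeltaAgeReport:
    deltas: pd.DataFrame              # subject_id, delta_pred, delta_ca
    correlation: float
    median_by_gap: dict[int, float]   # integer-year delta-CA bin -> median delta-pred

    def to_dict(self) -> dict:
        return {
            "correlation": self.correlation,
            "median_by_gap": {str(k): v for k, v in self.median_by_gap.items()},
            "n_subjects": int(len(self.deltas)),
        }


def _safe_r(a: np.ndarray, b: np.ndarray) -> float:
    def degenerate(x):
        return np.std(x) <= 1e-12 * (abs(np.mean(x)) + 1.0)

    if len(a) < 2 or degenerate(a) or degenerate(b):
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def subject_folds(subjects: np.ndarray, k: int, seed: int) -> dict[str, int]:
    """Deterministic subject-level fold assignment (repeat visits of one
    subject never straddle folds)."""
    uniq = sorted(pd.unique(subjects))
    if k > len(uniq):
        raise EvaluationError(f"k={k} exceeds number of subjects ({len(uniq)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    return {uniq[i]: int(f % k) for f, i in enumerate(perm)}


def kfold_cv(
    trainer,
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray | None = None,
    k: int = 7,
    seed: int = 0,
) -> CvReport:
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if subjects is None:
        subjects = np.array([f"s{i}" for i in range(n)])
    subjects = np.asarray(subjects)
    assign = subject_folds(subjects, k, seed)
    fold_of = np.array([assign[s] for s in subjects])

    pred = np.full(n, np.nan)
    fold_r, fold_mae = {}, {}
    for f in range(k):
        te = fold_of == f
        tr = ~te
        predict_fn = trainer(Xv[tr], y[tr])
        p = np.asarray(predict_fn(Xv[te]), dtype=float)
        pred[te] = p
        fold_r[str(f)] = _safe_r(p, y[te])
        fold_mae[str(f)] = float(np.mean(np.abs(p - y[te])))
    return CvReport(
        scheme="kfold",
        fold_r=fold_r,
        fold_mae=fold_mae,
        pooled_r=_safe_r(pred, y),
        pooled_mae=float(np.mean(np.abs(pred - y))),
        fold_assignment={s: str(f) for s, f in assign.items()},
        seed=seed,
        predictions=pd.DataFrame({"subject_id": subjects, "y": y, "pred": pred}),
    )


def loco_cv(
    trainer,
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    cohorts: np.ndarray,
) -> CvReport:
    """Each cohort held out in turn; r reported NaN for cohorts with
    constant age (birth-cohort analogue), MAE still computed."""
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cohorts = np.asarray(cohorts)
    labels = list(dict.fromkeys(cohorts))
    if len(labels) < 2:
        raise EvaluationError("LOCO needs at least 2 cohorts")
    pred = np.full(len(y), np.nan)
    fold_r, fold_mae = {}, {}
    for c in labels:
        te = cohorts == c
        tr = ~te
        predict_fn = trainer(Xv[tr], y[tr])
        p = np.asarray(predict_fn(Xv[te]), dtype=float)
        pred[te] = p
        fold_r[str(c)] = _safe_r(p, y[te])
        fold_mae[str(c)] = float(np.mean(np.abs(p - y[te])))
    return CvReport(
        scheme="loco",
        fold_r=fold_r,
        fold_mae=fold_mae,
        pooled_r=_safe_r(pred, y),
        pooled_mae=float(np.mean(np.abs(pred - y))),
        fold_assignment={str(c): str(c) for c in labels},
        predictions=pd.DataFrame({"cohort": cohorts, "y": y, "pred": pred}),
    )


def delta_age(
    score_fn,
    matrix: pd.DataFrame,
    pheno: pd.DataFrame,
    min_subjects: int = 10,
) -> DeltaAgeReport:
    """Within-subject change in predicted age vs change in chronological age
    for subjects with two visits.  ``score_fn(matrix_subset) -> scores``."""
    ph = pheno.set_index("sample_id")
    counts = matrix.groupby("subject_id")["visit"].nunique()
    repeat = counts[counts >= 2].index
    if len(repeat) == 0:
        raise EvaluationError("no subjects with repeat visits")
    if len(repeat) < min_subjects:
        raise EvaluationError(
            f"only {len(repeat)} subjects with repeat visits (< {min_subjects})"
        )
    sub = matrix[matrix["subject_id"].isin(repeat)].copy()
    scores = np.asarray(score_fn(sub), dtype=float)
    sub = sub.assign(_score=scores, _age=ph.loc[sub["sample_id"], "age"].to_numpy())

    rows = []
    for sid, g in sub.groupby("subject_id"):
        g = g.sort_values("visit")
        first, last = g.iloc[0], g.iloc[-1]
        d_ca = float(last["_age"] - first["_age"])
        rows.append((sid, float(last["_score"] - first["_score"]), d_ca))
    deltas = pd.DataFrame(rows, columns=["subject_id", "delta_pred", "delta_ca"])

    corr = _safe_r(deltas["delta_pred"].to_numpy(), deltas["delta_ca"].to_numpy())
    med = {}
    gap_bins = np.round(deltas["delta_ca"]).astype(int)
    for gap, g in deltas.groupby(gap_bins):
        med[int(gap)] = float(g["delta_pred"].median())
    return DeltaAgeReport(deltas=deltas, correlation=corr, median_by_gap=med)
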