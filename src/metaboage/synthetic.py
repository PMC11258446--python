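"""Synthetic multi-cohort metabolomic + phenotype data generator.

Produces wide sample x analyte concentration tables with the statistical
structure the downstream pipeline assumes: several cohorts with distinct
age windows, metabolites with linear and hinge-shaped age trends, a
latent-factor correlation structure (so collinearity pruning has work to
do), per-cohort multiplicative assay batch effects, cohort-level missing
analytes, multivariate location outliers, mortality-driving metabolites
(some concordant with their age trend, some opposing it), and repeat
visits for a subset of subjects.

Within-subject dependence is modelled with a subject random intercept per
analyte plus shared latent-factor scores; this is a stand-in — real
within-subject metabolite autocorrelation is not characterised here.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ID_COLS = ["sample_id", "subject_id", "cohort", "visit"]

PHENO_COLS = [
    "sample_id", "subject_id", "cohort", "visit", "age", "sex", "bmi",
    "ethnicity", "surv_time", "event",
]


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


class GenerationError(RuntimeError):
    """Non-finite values produced during generation."""


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic multi-cohort dataset.

    ``age_slopes`` are in concentration-SD per decade; ``mortality_loghr``
    in log hazard ratio per concentration-SD.  ``nonlinear_effects`` maps
    analyte index -> (knot age in years, slope change in SD/decade past
    the knot).  ``batch_factors`` has shape (n_cohorts, n_metabolites) and
    must be strictly positive.
    """

    n_cohorts: int = 8
    n_subjects: int = 400
    age_ranges: list[tuple[float, float]] = field(default_factory=list)
    n_metabolites: int = 98
    age_slopes: np.ndarray | None = None
    nonlinear_effects: dict[int, tuple[float, float]] = field(default_factory=dict)
    mortality_loghr: np.ndarray | None = None
    batch_factors: np.ndarray | None = None
    outlier_fraction: float = 0.0
    missing_analytes: dict[str, list[int]] = field(default_factory=dict)
    repeat_visit_fraction: float = 0.0
    follow_up_gap: float = 10.0
    censor_time: float = 15.0
    baseline_hazard: float = 0.02
    age_loghr: float = 0.06
    sex_loghr: float = -0.3
    survival_cohorts: list[str] | None = None
    female_fraction: float = 0.6
    n_latent: int = 5
    factor_scale: float = 0.45
    subject_sd: float = 0.3
    noise_sd: float = 0.6
    mixed_ethnicity_cohorts: list[str] = field(default_factory=list)
    riskfactor_effect: float = 0.4  # SD shift on smoking-linked analytes
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.age_ranges:
            self.age_ranges = default_age_ranges(self.n_cohorts)
        if len(self.age_ranges) != self.n_cohorts:
            raise ConfigError("age_ranges length must equal n_cohorts")
        p = self.n_metabolites
        if self.age_slopes is not None:
            self.age_slopes = np.asarray(self.age_slopes, dtype=float)
            if self.age_slopes.shape != (p,):
                raise ConfigError("age_slopes must have length n_metabolites")
        if self.mortality_loghr is not None:
            self.mortality_loghr = np.asarray(self.mortality_loghr, dtype=float)
            if self.mortality_loghr.shape != (p,):
                raise ConfigError("mortality_loghr must have length n_metabolites")
        if self.batch_factors is not None:
            self.batch_factors = np.asarray(self.batch_factors, dtype=float)
            if self.batch_factors.shape != (self.n_cohorts, p):
                raise ConfigError(
                    "batch_factors must have shape (n_cohorts, n_metabolites); got "
                    f"{self.batch_factors.shape}"
                )
            if not np.all(self.batch_factors > 0):
                raise ConfigError("batch_factors must be strictly positive")
        if not 0.0 <= self.outlier_fraction <= 0.1:
            raise ConfigError("outlier_fraction must be in [0, 0.1]")

    @property
    def cohort_names(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_cohorts)]

    @property
    def analyte_names(self) -> list[str]:
        return [f"met_{j + 1:03d}" for j in range(self.n_metabolites)]


def default_age_ranges(n_cohorts: int) -> list[tuple[float, float]]:
    """Cohort age windows whose union spans 24-86 years."""
    lo, hi = 24.0, 86.0
    if n_cohorts == 1:
        return [(lo, hi)]
    width = (hi - lo) * 0.45
    starts = np.linspace(lo, hi - width, n_cohorts)
    return [(float(s), float(min(s + width, hi))) for s in starts]


def default_config(
    n_cohorts: int = 8,
    n_subjects: int = 400,
    n_metabolites: int = 98,
    seed: int = 0,
    batch_sd: float = 0.0,
    outlier_fraction: float = 0.0,
    **kwargs,
) -> SimConfig:
    """Draw a reasonable random parameterisation.

    Roughly a third of analytes carry a linear age trend, a handful are
    hinge-shaped, and ~10 drive mortality; at least one mortality driver
    opposes its age trend so the opposing-direction penalty rule is
    exercised.
    """
    rng = np.random.default_rng(seed)
    p = n_metabolites
    slopes = np.zeros(p)
    n_age = max(3, p // 3)
    idx_age = rng.choice(p, size=n_age, replace=False)
    slopes[idx_age] = rng.uniform(0.1, 0.4, size=n_age) * rng.choice([-1, 1], size=n_age)

    nonlinear: dict[int, tuple[float, float]] = {}
    for j in idx_age[: max(2, n_age // 6)]:
        nonlinear[int(j)] = (float(rng.uniform(50, 65)), float(rng.uniform(0.2, 0.5)))

    loghr = np.zeros(p)
    n_mort = min(10, p)
    idx_mort = rng.choice(idx_age, size=min(n_mort, len(idx_age)), replace=False)
    loghr[idx_mort] = rng.uniform(0.15, 0.4, size=len(idx_mort)) * np.sign(slopes[idx_mort])
    # force at least one analyte whose mortality effect opposes its age trend
    j_oppose = int(idx_mort[0])
    loghr[j_oppose] = -abs(loghr[j_oppose]) * np.sign(slopes[j_oppose])

    if batch_sd > 0:
        batch = np.exp(rng.normal(0.0, batch_sd, size=(n_cohorts, p)))
    else:
        batch = np.ones((n_cohorts, p))

    return SimConfig(
        n_cohorts=n_cohorts,
        n_subjects=n_subjects,
        n_metabolites=p,
        age_slopes=slopes,
        nonlinear_effects=nonlinear,
        mortality_loghr=loghr,
        batch_factors=batch,
        outlier_fraction=outlier_fraction,
        seed=seed,
        **kwargs,
    )


@dataclass
class TruthRecord:
    """Every generative parameter, for parameter-recovery tests.

    Together with the seed this fully determines the generated tables.
    """

    config: SimConfig
    baselines: np.ndarray
    loadings: np.ndarray            # (n_latent, p)
    sex_effects: np.ndarray
    bmi_effects: np.ndarray
    smoke_effects: np.ndarray
    age_slopes: np.ndarray
    nonlinear_effects: dict[int, tuple[float, float]]
    mortality_loghr: np.ndarray
    batch_factors: np.ndarray
    outlier_samples: list[str]
    subject_factors: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    subject_intercepts: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, SimConfig):
                d = dataclasses.asdict(o)
                return {k: enc(v) for k, v in d.items()}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o

        d = {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}
        return json.dumps(d, indent=1)


def _age_effect(truth_slopes, nonlinear, ages, p):
    """Per-analyte age contribution in concentration units (SD scale)."""
    eff = np.outer((ages - 55.0) / 10.0, truth_slopes)
    for j, (knot, delta) in nonlinear.items():
        eff[:, j] += np.maximum(0.0, ages - knot) / 10.0 * delta
    return eff


def generate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate (MetaboliteMatrix, PhenoTable, TruthRecord) at visit 1.

    Metabolite j of sample i is
    ``baseline_j + age_effect_j(age_i) + subject_factors_i @ loadings_j +
    subject_intercept_ij + sex/BMI effects + noise`` and is then multiplied
    by ``batch_factors[cohort, j]``.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_metabolites
    analytes = config.analyte_names

    baselines = rng.uniform(5.0, 15.0, size=p)
    loadings = rng.normal(0.0, config.factor_scale, size=(config.n_latent, p))
    sex_effects = rng.normal(0.0, 0.15, size=p)
    bmi_effects = rng.normal(0.0, 0.04, size=p)
    slopes = config.age_slopes if config.age_slopes is not None else np.zeros(p)

    # a binary risk factor (smoking analogue) shifting a few age-signal
    # analytes, so CA-adjusted association analyses have signal to find
    smoke_effects = np.zeros(p)
    signal = np.flatnonzero(np.asarray(slopes) != 0)
    smoke_targets = signal[:3] if len(signal) >= 3 else np.arange(min(3, p))
    smoke_effects[smoke_targets] = config.riskfactor_effect

    pheno_rows = []
    data_blocks = []
    subject_factors: dict[str, np.ndarray] = {}
    subject_intercepts: dict[str, np.ndarray] = {}

    for c, cohort in enumerate(config.cohort_names):
        n = config.n_subjects
        lo, hi = config.age_ranges[c]
        ages = rng.uniform(lo, hi, size=n)
        sex = (rng.random(n) < config.female_fraction).astype(int)
        bmi = np.clip(rng.normal(27.0, 4.0, size=n), 16.0, 48.0)
        if cohort in config.mixed_ethnicity_cohorts:
            eth = np.where(rng.random(n) < 0.35, "SA", "EUR")
        else:
            eth = np.full(n, "EUR", dtype=object)

        f = rng.normal(0.0, 1.0, size=(n, config.n_latent))
        b = rng.normal(0.0, config.subject_sd, size=(n, p))
        eps = rng.normal(0.0, 1.0, size=(n, p)) * config.noise_sd
        smoker = (rng.random(n) < 0.25).astype(int)
        inactive = (rng.random(n) < 0.3).astype(int)  # metabolome-null factor
        sbp = 105.0 + 0.55 * ages + 6.0 * (bmi - 27.0) / 4.0 + rng.normal(0, 9.0, n)
        egfr = 125.0 - 0.75 * ages + rng.normal(0, 8.0, n)
        crp = np.exp(rng.normal(0.0, 0.8, n) + 0.012 * (ages - 55.0))

        X = (
            baselines[None, :]
            + _age_effect(slopes, config.nonlinear_effects, ages, p)
            + sex[:, None] * sex_effects[None, :]
            + (bmi - 27.0)[:, None] * bmi_effects[None, :]
            + smoker[:, None] * smoke_effects[None, :]
            + f @ loadings
            + b
            + eps
        )

        subj_ids = [f"{cohort}_S{i + 1:05d}" for i in range(n)]
        for sid, fi, bi in zip(subj_ids, f, b):
            subject_factors[sid] = fi
            subject_intercepts[sid] = bi

        pheno_rows.append(
            pd.DataFrame(
                {
                    "sample_id": [s + "_v1" for s in subj_ids],
                    "subject_id": subj_ids,
                    "cohort": cohort,
                    "visit": 1,
                    "age": ages,
                    "sex": sex,
                    "bmi": bmi,
                    "ethnicity": eth,
                    "rf_smoking": smoker,
                    "rf_inactive": inactive,
                    "rf_obesity": (bmi > 30).astype(int),
                    "bio_sbp": sbp,
                    "bio_egfr": egfr,
                    "bio_crp": crp,
                }
            )
        )
        data_blocks.append(X)

    X = np.vstack(data_blocks)
    pheno = pd.concat(pheno_rows, ignore_index=True)

    # location outliers: shift along a random direction, 6 robust SDs per
    # coordinate in RMS terms, before batch scaling
    outlier_samples: list[str] = []
    n_total = len(pheno)
    n_out = int(round(config.outlier_fraction * n_total))
    if n_out > 0:
        idx = rng.choice(n_total, size=n_out, replace=False)
        med = np.median(X, axis=0)
        mad = np.median(np.abs(X - med), axis=0) * 1.4826
        mad = np.where(mad > 0, mad, 1.0)
        for i in idx:
            u = rng.normal(size=p)
            u = u / np.linalg.norm(u) * np.sqrt(p)
            X[i] = X[i] + 6.0 * mad * u
        outlier_samples = pheno.loc[np.sort(idx), "sample_id"].tolist()

    if not np.all(np.isfinite(X)):
        raise GenerationError("non-finite metabolite values generated")

    # per-cohort multiplicative batch effect
    batch = config.batch_factors if config.batch_factors is not None else np.ones((config.n_cohorts, p))
    for c, cohort in enumerate(config.cohort_names):
        mask = (pheno["cohort"] == cohort).to_numpy()
        X[mask] = X[mask] * batch[c][None, :]

    matrix = pd.concat(
        [pheno[ID_COLS].copy(), pd.DataFrame(X, columns=analytes)], axis=1
    )

    # cohort-level missing analytes
    for cohort, js in config.missing_analytes.items():
        mask = matrix["cohort"] == cohort
        for j in js:
            matrix.loc[mask, analytes[j]] = np.nan

    pheno["surv_time"] = np.nan
    pheno["event"] = np.nan

    truth = TruthRecord(
        config=config,
        baselines=baselines,
        loadings=loadings,
        sex_effects=sex_effects,
        bmi_effects=bmi_effects,
        smoke_effects=smoke_effects,
        age_slopes=np.asarray(slopes, dtype=float),
        nonlinear_effects=dict(config.nonlinear_effects),
        mortality_loghr=(
            config.mortality_loghr if config.mortality_loghr is not None else np.zeros(p)
        ),
        batch_factors=np.asarray(batch, dtype=float),
        outlier_samples=outlier_samples,
        subject_factors=subject_factors,
        subject_intercepts=subject_intercepts,
    )
    return matrix, pheno, truth


def simulate_survival(
    pheno: pd.DataFrame, matrix: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Attach exponential survival times under a proportional-hazards model.

    hazard = h0 * exp(age_loghr*(age-55) + sex_loghr*sex + sum_j loghr_j * z_ij)
    with per-cohort z-scored analytes and administrative censoring at
    ``censor_time``.  Cohorts outside ``survival_cohorts`` keep NaN outcomes.
    """
    rng = np.random.default_rng(config.seed + 7919)
    pheno = pheno.copy()
    loghr = (
        config.mortality_loghr
        if config.mortality_loghr is not None
        else np.zeros(config.n_metabolites)
    )
    analytes = config.analyte_names
    surv_cohorts = (
        config.survival_cohorts if config.survival_cohorts is not None else config.cohort_names
    )
    for cohort in config.cohort_names:
        mask = (pheno["cohort"] == cohort) & (pheno["visit"] == 1)
        if cohort not in surv_cohorts:
            continue
        by_sample = matrix.set_index("sample_id")
        sub = by_sample.loc[pheno.loc[mask, "sample_id"], analytes]
        vals = sub.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN analytes
            mean = np.nanmean(vals, axis=0)
            sd = np.nanstd(vals, axis=0)
        mean = np.where(np.isfinite(mean), mean, 0.0)
        sd = np.where(np.isfinite(sd) & (sd > 0), sd, 1.0)
        z = (vals - mean) / sd
        z = np.where(np.isfinite(z), z, 0.0)
        eta = (
            config.age_loghr * (pheno.loc[mask, "age"].to_numpy() - 55.0)
            + config.sex_loghr * pheno.loc[mask, "sex"].to_numpy()
            + z @ loghr
        )
        haz = config.baseline_hazard * np.exp(eta)
        if not np.all(np.isfinite(haz)):
            raise GenerationError("non-finite hazard in survival simulation")
        u = rng.random(mask.sum())
        t = -np.log(u) / np.maximum(haz, 1e-300)
        event = (t <= config.censor_time).astype(float)
        surv = np.minimum(t, config.censor_time)
        surv = np.maximum(surv, 1e-8)
        pheno.loc[mask, "surv_time"] = surv
        pheno.loc[mask, "event"] = event
    return pheno


def add_longitudinal_visits(
    matrix: pd.DataFrame,
    pheno: pd.DataFrame,
    config: SimConfig,
    truth: TruthRecord,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Give a random subset of subjects a second visit at age + follow_up_gap.

    Metabolites advance along their generating age trajectories with the
    same subject effects and fresh noise.
    """
    if config.repeat_visit_fraction <= 0:
        return matrix, pheno
    rng = np.random.default_rng(config.seed + 104729)
    p = config.n_metabolites
    analytes = config.analyte_names
    batch = truth.batch_factors
    cohort_index = {c: i for i, c in enumerate(config.cohort_names)}

    base = pheno[pheno["visit"] == 1]
    n_pick = int(round(config.repeat_visit_fraction * len(base)))
    if n_pick == 0:
        return matrix, pheno
    pick = rng.choice(len(base), size=n_pick, replace=False)
    rows = base.iloc[np.sort(pick)]

    ages2 = rows["age"].to_numpy() + config.follow_up_gap
    f = np.stack([truth.subject_factors[s] for s in rows["subject_id"]])
    b = np.stack([truth.subject_intercepts[s] for s in rows["subject_id"]])
    eps = rng.normal(0.0, 1.0, size=(len(rows), p)) * config.noise_sd
    X2 = (
        truth.baselines[None, :]
        + _age_effect(truth.age_slopes, truth.nonlinear_effects, ages2, p)
        + rows["sex"].to_numpy()[:, None] * truth.sex_effects[None, :]
        + (rows["bmi"].to_numpy() - 27.0)[:, None] * truth.bmi_effects[None, :]
        + rows["rf_smoking"].to_numpy()[:, None] * truth.smoke_effects[None, :]
        + f @ truth.loadings
        + b
        + eps
    )
    for cohort in rows["cohort"].unique():
        m = (rows["cohort"] == cohort).to_numpy()
        X2[m] = X2[m] * batch[cohort_index[cohort]][None, :]

    sid2 = [s + "_v2" for s in rows["subject_id"]]
    mat2 = pd.DataFrame(
        {
            "sample_id": sid2,
            "subject_id": rows["subject_id"].to_numpy(),
            "cohort": rows["cohort"].to_numpy(),
            "visit": 2,
        }
    )
    mat2 = pd.concat([mat2, pd.DataFrame(X2, columns=analytes, index=mat2.index)], axis=1)
    for cohort, js in config.missing_analytes.items():
        mask = mat2["cohort"] == cohort
        for j in js:
            mat2.loc[mask, analytes[j]] = np.nan

    ph2 = rows.copy()
    ph2["sample_id"] = sid2
    ph2["visit"] = 2
    ph2["age"] = ages2
    ph2["surv_time"] = np.nan
    ph2["event"] = np.nan

    matrix_out = pd.concat([matrix, mat2], ignore_index=True)
    pheno_out = pd.concat([pheno, ph2], ignore_index=True)
    return matrix_out, pheno_out


def analyte_columns(matrix: pd.DataFrame) -> list[str]:
    """Columns of a MetaboliteMatrix that hold analyte concentrations."""
    return [c for c in matrix.columns if c not in ID_COLS]
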