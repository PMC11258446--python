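"""End-to-end pipeline: simulate -> preprocess -> MWAS -> model fitting ->
evaluation -> association analyses, with a manifest of every output hash.

A single ``seed`` in the configuration drives every stochastic choice
(simulation, CV folds, lambda search), so a rerun with the same config is
byte-identical.  Per-stage logs record sample/analyte counts in and out of
every filter.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from . import evaluation as ev
from . import io as mio
from . import models as mdl
from . import mwas as mw
from . import preprocess as pp
from . import synthetic as syn

log = logging.getLogger("metaboage")

STAGES = ["simulate", "preprocess", "mwas", "fit", "evaluate", "associate"]


class DependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 17
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # simulation scale
    n_cohorts: int = 6
    n_subjects: int = 300
    n_metabolites: int = 40
    batch_sd: float = 0.15
    outlier_fraction: float = 0.01
    repeat_visit_fraction: float = 0.15
    # thresholds (paper-anchored defaults)
    missing_rule: float = 0.2
    replicate_r_threshold: float = 0.7
    outlier_weight_threshold: float = 0.1
    vif_threshold: float = 5.0
    alpha: float = 0.5
    fdr_threshold: float = 0.05
    report_p: float = 0.001
    k_folds: int = 7
    knn_k: int = 10
    mars_max_terms: int = 15
    mars_max_knots: int = 15
    reference_cohort: str | None = None   # default: middle cohort (mixed-sex, mid-age)
    age_bins: list[tuple[float, float]] | None = None

    def validate(self) -> None:
        if not 0 <= self.missing_rule <= 1:
            raise ValueError("missing_rule must be in [0, 1]")
        if not 0 <= self.outlier_weight_threshold <= 1:
            raise ValueError("outlier_weight_threshold must be in [0, 1]")
        if self.vif_threshold <= 1:
            raise ValueError("vif_threshold must exceed 1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        cfg = cls(**data)
        if cfg.age_bins is not None:
            cfg.age_bins = [tuple(b) for b in cfg.age_bins]
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the enabled stages in order, writing versioned outputs plus a
    manifest with the SHA-256 of every artifact.  A stage failure halts the
    run with the manifest recording the stages completed so far."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": [], "files": {}}
    stages = set(config.stages)

    def save_table(df, name):
        p = out / name
        mio.write_table(df, p)
        manifest["files"][name] = mio.sha256_file(p)

    def save_json(obj, name):
        p = out / name
        mio.write_json(obj, p)
        manifest["files"][name] = mio.sha256_file(p)

    def finish():
        mio.write_json(manifest, out / "manifest.json")
        return out

    try:
        # ---- simulate ---------------------------------------------------
        if "simulate" not in stages:
            raise DependencyError("pipeline currently requires the simulate stage")
        sim_cfg = syn.default_config(
            n_cohorts=config.n_cohorts,
            n_subjects=config.n_subjects,
            n_metabolites=config.n_metabolites,
            seed=config.seed,
            batch_sd=config.batch_sd,
            outlier_fraction=config.outlier_fraction,
            repeat_visit_fraction=config.repeat_visit_fraction,
            survival_cohorts=None,
            mixed_ethnicity_cohorts=["C02"],
        )
        matrix, pheno, truth = syn.generate(sim_cfg)
        pheno = syn.simulate_survival(pheno, matrix, sim_cfg)
        matrix, pheno = syn.add_longitudinal_visits(matrix, pheno, sim_cfg, truth)
        log.info("simulate: %d samples x %d analytes", len(matrix), sim_cfg.n_metabolites)
        save_table(matrix, "matrix_raw.csv")
        save_table(pheno, "pheno.csv")
        (out / "truth.json").write_text(truth.to_json())
        manifest["files"]["truth.json"] = mio.sha256_file(out / "truth.json")
        manifest["stages"].append("simulate")

        analytes = syn.analyte_columns(matrix)
        pruned_analytes = analytes
        qc = None
        if "preprocess" in stages:
            qc = pp.filter_variables(matrix, missing_rule=config.missing_rule,
                                     r_threshold=config.replicate_r_threshold)
            kept = ["sample_id", "subject_id", "cohort", "visit"] + qc.retained_analytes
            matrix = matrix[kept]
            out_rep = pp.detect_outliers(
                matrix, weight_threshold=config.outlier_weight_threshold
            )
            n_before = len(matrix)
            matrix = pp.drop_outliers(matrix, out_rep)
            pheno = pheno[pheno["sample_id"].isin(matrix["sample_id"])].reset_index(drop=True)
            log.info("preprocess: analytes %d -> %d; samples %d -> %d",
                     len(analytes), len(qc.retained_analytes), n_before, len(matrix))
            reference = config.reference_cohort or sim_cfg.cohort_names[len(sim_cfg.cohort_names) // 2]
            matrix, calib = pp.calibrate_cohorts(matrix, pheno, reference)
            matrix = pp.knn_impute(matrix, k=config.knn_k)
            vif = pp.vif_prune(matrix, threshold=config.vif_threshold)
            pruned_analytes = vif.retained
            save_table(matrix, "matrix_calibrated.csv")
            save_json({"qc": qc.to_dict(), "outliers": out_rep.to_dict()}, "qc_report.json")
            save_json(calib.to_dict(), "calibration.json")
            save_json(vif.to_dict(), "vif_trace.json")
            manifest["stages"].append("preprocess")

        age_meta = mort_meta = None
        if "mwas" in stages:
            age_eff = mw.mwas_age(matrix, pheno)
            age_meta = mw.meta_fixed(age_eff)
            strat_eff = mw.mwas_age_stratified(matrix, pheno, bins=config.age_bins)
            strat_meta = mw.meta_fixed(strat_eff)
            mort_eff = mw.mwas_mortality(matrix, pheno)
            mort_meta = mw.meta_fixed(mort_eff) if mort_eff else []
            save_table(mw.meta_to_frame(age_meta), "mwas_age_meta.csv")
            save_table(mw.meta_to_frame(strat_meta), "mwas_age_stratified_meta.csv")
            if mort_meta:
                save_table(mw.meta_to_frame(mort_meta), "mwas_mortality_meta.csv")
            manifest["stages"].append("mwas")

        models: dict[str, mdl.AgingModel] = {}
        if "fit" in stages:
            Xp = matrix[pruned_analytes]
            age = pheno.set_index("sample_id").loc[matrix["sample_id"], "age"].to_numpy()
            models["elastic_net"] = mdl.fit_elastic_net_age(
                Xp, age, alpha=config.alpha, seed=config.seed
            )
            models["mars"] = mdl.fit_mars_age(
                Xp, age, max_terms=config.mars_max_terms,
                max_knots_per_var=config.mars_max_knots, seed=config.seed,
            )
            if "mwas" not in stages or not mort_meta:
                raise DependencyError(
                    "phenotypic-age fitting requires the mwas stage (mortality "
                    "meta-analysis p-values are its penalty factors); enable 'mwas'"
                )
            pf = mdl.mortality_penalty_factors(age_meta, mort_meta, pruned_analytes)
            models["phenotypic"] = mdl.fit_phenotypic_age(
                Xp, age, pf, alpha=config.alpha, seed=config.seed
            )
            ph_idx = pheno.set_index("sample_id").loc[matrix["sample_id"]]
            has_surv = np.isfinite(ph_idx["surv_time"].to_numpy(dtype=float))
            covs = ph_idx.loc[has_surv, ["age", "sex", "bmi", "ethnicity", "cohort"]]
            models["mortality_score"] = mdl.fit_mortality_score(
                Xp[has_surv], covs,
                ph_idx.loc[has_surv, "surv_time"].to_numpy(),
                ph_idx.loc[has_surv, "event"].to_numpy(),
                alpha=config.alpha, seed=config.seed,
            )
            for name, m in models.items():
                p = out / f"model_{name}.json"
                p.write_text(m.to_json())
                manifest["files"][p.name] = mio.sha256_file(p)
            manifest["stages"].append("fit")

        if "evaluate" in stages:
            if not models:
                raise DependencyError("evaluate requires the fit stage")
            base = matrix[matrix["visit"] == 1]
            age = pheno.set_index("sample_id").loc[base["sample_id"], "age"].to_numpy()
            Xb = base[pruned_analytes]
            rows = []
            for name in ("elastic_net", "phenotypic", "mars"):
                trainer = _trainer_for(name, models[name], config)
                rep = ev.kfold_cv(trainer, Xb, age, base["subject_id"].to_numpy(),
                                  k=config.k_folds, seed=config.seed)
                loco = ev.loco_cv(trainer, Xb, age, base["cohort"].to_numpy())
                rows.append({"model": name, "scheme": "kfold", **rep.to_dict()})
                rows.append({"model": name, "scheme": "loco", **loco.to_dict()})
            save_json({"cv": rows}, "evaluation.json")
            dmodel = models["mars"]
            try:
                drep = ev.delta_age(lambda m: mdl.predict_age(dmodel, m), matrix, pheno)
                save_json(drep.to_dict(), "delta_age.json")
            except ev.EvaluationError as exc:
                log.warning("delta-age skipped: %s", exc)
            manifest["stages"].append("evaluate")

        if "associate" in stages:
            if not models:
                raise DependencyError("associate requires the fit stage")
            results = []
            for name, m in models.items():
                scores = mdl.predict_age(m, matrix)
                ph = pheno.set_index("sample_id").loc[matrix["sample_id"]].reset_index()
                for rf in ("rf_smoking", "rf_inactive", "rf_obesity"):
                    results.append(assoc.riskfactor_assoc(scores, ph, rf, score_name=name))
                for bm in ("bio_sbp", "bio_egfr", "bio_crp"):
                    results.append(assoc.biomarker_assoc(scores, ph, bm, score_name=name))
                try:
                    results.extend(assoc.cox_event_assoc(
                        scores, ph, score_name=name, event_name="all_cause_mortality"
                    ))
                except assoc.AssociationError as exc:
                    log.warning("cox association skipped for %s: %s", name, exc)
            save_table(assoc.assoc_to_frame(results), "associations.csv")
            manifest["stages"].append("associate")
    except Exception:
        mio.write_json(manifest, out / "manifest.json")
        raise
    return finish()


def _trainer_for(name: str, template: mdl.AgingModel, config: PipelineConfig):
    """Refitting trainer closures for cross-validation."""
    cols = template.analytes

    if name == "mars":
        def trainer(X, y):
            m = mdl.fit_mars_age(pd.DataFrame(X, columns=cols), y,
                                 max_terms=config.mars_max_terms,
                                 max_knots_per_var=config.mars_max_knots)
            return lambda Xt: mdl.predict_age(m, pd.DataFrame(Xt, columns=cols))
        return trainer

    pf = template.penalty_factors

    def trainer(X, y):
        m = mdl.fit_elastic_net_age(
            pd.DataFrame(X, columns=cols), y, alpha=config.alpha,
            penalty_factors=pf, seed=config.seed,
            kind="phenotypic" if pf is not None else "elastic_net",
        )
        return lambda Xt: mdl.predict_age(m, pd.DataFrame(Xt, columns=cols))
    return trainer
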