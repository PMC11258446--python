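import numpy as np
import pandas as pd
import pytest

from metaboage import models as mdl
from metaboage import mwas as mw
from metaboage import synthetic as syn


def _meta(analyte, beta, p):
    return mw.MetaResult(analyte=analyte, beta_pooled=beta, se_pooled=0.1,
                         z=beta / 0.1, p=p, Q_stat=0.0, df=0, I2=0.0, k=1)


def _frame(X):
    return pd.DataFrame(X, columns=[f"met_{j + 1:03d}" for j in range(X.shape[1])])


class TestElasticNetAge:
    def test_near_ols_in_unpenalized_limit(self, rng):
        from metaboage import enet
        X = rng.normal(size=(1000, 3))
        age = 50 + X @ np.array([2.0, -1.0, 0.5]) + rng.normal(0, 1, 1000)
        path = enet.fit_path(X, age, alpha=0.5, lambdas=np.array([1e-9]))
        Xd = np.column_stack([np.ones(1000), X])
        beta, *_ = np.linalg.lstsq(Xd, age, rcond=None)
        assert np.allclose(path.coefs[0], beta[1:], atol=1e-3)

    def test_model_kind_and_refit_consistency(self, rng):
        X = _frame(rng.normal(size=(300, 5)))
        age = 50 + X["met_001"] * 3 + rng.normal(0, 2, 300)
        m = mdl.fit_elastic_net_age(X, age, seed=1)
        assert m.kind == "elastic_net"
        pred = mdl.predict_age(m, X.assign(sample_id="x", cohort="c"))
        assert np.allclose(pred, X.to_numpy() @ m.coefficients + m.intercept)

    def test_seed_determinism(self, rng):
        X = _frame(rng.normal(size=(200, 4)))
        age = 40 + X["met_002"] + rng.normal(0, 1, 200)
        m1 = mdl.fit_elastic_net_age(X, age, seed=9)
        m2 = mdl.fit_elastic_net_age(X, age, seed=9)
        assert np.array_equal(m1.coefficients, m2.coefficients)
        assert m1.intercept == m2.intercept


class TestMortalityPenaltyFactors:
    def test_concordant_uses_p_value(self):
        v = mdl.mortality_penalty_factors(
            [_meta("a", 0.5, 0.01)], [_meta("a", 0.3, 0.001)], ["a"])
        assert v[0] == pytest.approx(0.001)

    def test_opposing_signs_forced_to_one(self):
        v = mdl.mortality_penalty_factors(
            [_meta("a", 0.5, 0.01)], [_meta("a", -0.3, 1e-8)], ["a"])
        assert v[0] == 1.0

    def test_p_one_concordant_is_one(self):
        v = mdl.mortality_penalty_factors(
            [_meta("a", 0.5, 0.5)], [_meta("a", 0.3, 1.0)], ["a"])
        assert v[0] == 1.0

    def test_missing_analyte_named_in_error(self):
        with pytest.raises(mdl.ModelError, match="zzz"):
            mdl.mortality_penalty_factors(
                [_meta("zzz", 1, 0.1)], [_meta("other", 1, 0.1)], ["zzz"])


class TestPhenotypicAge:
    def test_uniform_penalties_equal_plain_fit(self, rng):
        X = _frame(rng.normal(size=(300, 5)))
        age = 50 + X["met_001"] * 2 - X["met_004"] + rng.normal(0, 1, 300)
        plain = mdl.fit_elastic_net_age(X, age, seed=2)
        pheno = mdl.fit_phenotypic_age(X, age, np.full(5, 0.37), seed=2)
        assert np.allclose(plain.coefficients, pheno.coefficients, atol=1e-10)
        assert pheno.kind == "phenotypic"

    def test_mortality_linked_analyte_shrunk_less(self):
        keep = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 600
            sig = r.normal(size=n)
            X = _frame(np.column_stack([
                sig + r.normal(0, 0.8, n),       # mortality-linked (v ~ 0)
                sig + r.normal(0, 0.8, n),       # identical signal, null (v = 1)
                r.normal(size=(n, 2)),
            ]))
            age = 50 + 3 * sig + r.normal(0, 1, n)
            v = np.array([0.001, 1.0, 1.0, 1.0])
            m = mdl.fit_phenotypic_age(X, age, v, seed=seed)
            keep += abs(m.coefficients[0]) >= abs(m.coefficients[1])
        assert keep >= 16

    def test_opposing_analyte_not_larger_than_plain(self, rng):
        # penalty monotonicity holds at fixed lambda: raising an analyte's
        # relative multiplier can only shrink its coefficient further
        from metaboage import enet
        X = rng.normal(size=(500, 4))
        age = 50 + X[:, 0] * 2 + rng.normal(0, 1, 500)
        lams = np.array([0.5, 0.1, 0.02])
        plain = enet.fit_path(X, age, alpha=0.5, lambdas=lams)
        v = np.array([1.0, 0.5, 0.5, 0.5])  # analyte 1 penalized hardest
        phen = enet.fit_path(X, age, alpha=0.5, penalty_factors=v, lambdas=lams)
        assert np.all(np.abs(phen.coefs[:, 0]) <= np.abs(plain.coefs[:, 0]) + 1e-9)


class TestRescale:
    def test_exact_target_mean_sd(self, rng):
        s = rng.normal(0, 1, 500)
        ages = rng.normal(50, 10, 500)
        out = mdl.rescale_to_age_units(s, ages)
        assert out.mean() == pytest.approx(ages.mean())
        assert out.std() == pytest.approx(ages.std())

    def test_rank_preserved(self, rng):
        s = rng.normal(size=100)
        out = mdl.rescale_to_age_units(s, rng.normal(50, 10, 100))
        assert np.array_equal(np.argsort(s), np.argsort(out))

    def test_idempotent(self, rng):
        s = rng.normal(size=200)
        ages = rng.normal(55, 8, 200)
        once = mdl.rescale_to_age_units(s, ages)
        twice = mdl.rescale_to_age_units(once, ages)
        assert np.allclose(once, twice, atol=1e-10)

    def test_constant_scores_rejected(self):
        with pytest.raises(mdl.ModelError, match="constant"):
            mdl.rescale_to_age_units(np.ones(10), np.arange(10.0))


class TestMortalityScore:
    @pytest.fixture(scope="class")
    def surv_data(self):
        cfg = syn.default_config(n_cohorts=2, n_subjects=1500, n_metabolites=10,
                                 seed=30)
        loghr = np.zeros(10)
        loghr[1] = 0.4
        cfg.mortality_loghr = loghr
        m, ph, _ = syn.generate(cfg)
        ph = syn.simulate_survival(ph, m, cfg)
        return cfg, m, ph

    def test_driving_analyte_positive_and_held_out_hr(self, surv_data):
        from lifelines import CoxPHFitter
        cfg, m, ph = surv_data
        half = len(m) // 2
        tr_m, te_m = m.iloc[:half], m.iloc[half:]
        tr_p = ph.set_index("sample_id").loc[tr_m["sample_id"]]
        te_p = ph.set_index("sample_id").loc[te_m["sample_id"]]
        model = mdl.fit_mortality_score(
            tr_m[cfg.analyte_names],
            tr_p[["age", "sex", "bmi", "ethnicity", "cohort"]],
            tr_p["surv_time"].to_numpy(), tr_p["event"].to_numpy(), seed=0,
        )
        assert model.coefficients[1] > 0
        score = mdl.predict_age(model, te_m)
        z = (score - score.mean()) / score.std()
        df = pd.DataFrame({"s": z, "age": te_p["age"].to_numpy(),
                           "surv_time": te_p["surv_time"].to_numpy(),
                           "event": te_p["event"].to_numpy()})
        cph = CoxPHFitter().fit(df, "surv_time", "event")
        assert np.exp(cph.params_["s"]) > 1.0
        assert cph.summary.loc["s", "p"] < 0.001

    def test_training_score_rescaled_to_age_moments(self, surv_data):
        cfg, m, ph = surv_data
        phi = ph.set_index("sample_id").loc[m["sample_id"]]
        model = mdl.fit_mortality_score(
            m[cfg.analyte_names], phi[["age", "sex", "bmi", "ethnicity", "cohort"]],
            phi["surv_time"].to_numpy(), phi["event"].to_numpy(), seed=0,
        )
        scores = mdl.predict_age(model, m)
        ages = phi["age"].to_numpy()
        assert scores.mean() == pytest.approx(ages.mean(), abs=1e-8)
        assert scores.std() == pytest.approx(ages.std(), abs=1e-8)

    def test_no_events_raises(self, rng):
        X = _frame(rng.normal(size=(100, 3)))
        cov = pd.DataFrame({"age": rng.uniform(40, 70, 100), "sex": 0, "bmi": 27.0})
        with pytest.raises(mdl.ModelError, match="events"):
            mdl.fit_mortality_score(X, cov, np.ones(100), np.zeros(100))

    def test_null_hazard_ci_covers_one(self):
        from lifelines import CoxPHFitter
        covered = 0
        for seed in range(10):
            cfg = syn.default_config(n_cohorts=1, n_subjects=700,
                                     n_metabolites=6, seed=400 + seed)
            cfg.mortality_loghr = np.zeros(6)
            m, ph, _ = syn.generate(cfg)
            ph = syn.simulate_survival(ph, m, cfg)
            half = len(m) // 2
            tr_p = ph.iloc[:half]
            te_p = ph.iloc[half:]
            try:
                model = mdl.fit_mortality_score(
                    m.iloc[:half][cfg.analyte_names],
                    tr_p[["age", "sex", "bmi"]],
                    tr_p["surv_time"].to_numpy(), tr_p["event"].to_numpy(),
                    seed=seed,
                )
            except mdl.ModelError:
                covered += 1  # all-zero score: no association estimable
                continue
            score = mdl.predict_age(model, m.iloc[half:])
            if score.std() == 0:
                covered += 1
                continue
            df = pd.DataFrame({"s": (score - score.mean()) / score.std(),
                               "age": te_p["age"].to_numpy(),
                               "surv_time": te_p["surv_time"].to_numpy(),
                               "event": te_p["event"].to_numpy()})
            cph = CoxPHFitter().fit(df, "surv_time", "event")
            lo, hi = cph.confidence_intervals_.loc["s"]
            covered += lo <= 0 <= hi
        assert covered >= 9


class TestCoefficientTable:
    def test_csv_roundtrip(self):
        t = mdl.CoefficientTable(["a", "b"], [0.5, -0.5], ["log", "none"],
                                 ["cohort_z", "none"], "to_age_units")
        t2 = mdl.CoefficientTable.from_csv(t.to_csv())
        assert t2.analytes == t.analytes
        assert np.allclose(t2.weights, t.weights)
        assert t2.rescale_rule == "to_age_units"

    def test_duplicate_analytes_rejected(self):
        with pytest.raises(mdl.ModelError):
            mdl.CoefficientTable(["a", "a"], [1, 2], ["none"] * 2, ["none"] * 2)

    def test_template_schema(self):
        t = mdl.deelen_style_template([f"met_{i:03d}" for i in range(1, 20)])
        assert len(t.analytes) == 14
        assert all(tr == "log" for tr in t.transforms)
        assert all(sc == "cohort_z" for sc in t.scalings)
        assert t.rescale_rule == "to_age_units"


class TestApplyCoefficientTable:
    def _tiny(self):
        m = pd.DataFrame({
            "sample_id": ["s1", "s2", "s3"],
            "subject_id": ["s1", "s2", "s3"],
            "cohort": "A", "visit": 1,
            "met_001": [1.0, 2.0, 3.0],
            "met_002": [4.0, 5.0, 9.0],
        })
        ph = m[["sample_id", "cohort"]].assign(age=[40.0, 50.0, 60.0])
        return m, ph

    def test_hand_computed_weighted_zsum(self):
        m, ph = self._tiny()
        t = mdl.CoefficientTable(["met_001", "met_002"], [0.5, -0.5],
                                 ["none", "none"], ["cohort_z", "cohort_z"])
        s = mdl.apply_coefficient_table(m, ph, t)
        x1 = m["met_001"].to_numpy()
        x2 = m["met_002"].to_numpy()
        z1 = (x1 - x1.mean()) / x1.std()
        z2 = (x2 - x2.mean()) / x2.std()
        assert np.allclose(s, 0.5 * z1 - 0.5 * z2)

    def test_zero_weights_rescale_error_surfaces(self):
        m, ph = self._tiny()
        t = mdl.CoefficientTable(["met_001"], [0.0], ["none"], ["none"],
                                 rescale_rule="to_age_units")
        with pytest.raises(mdl.ModelError, match="constant"):
            mdl.apply_coefficient_table(m, ph, t)

    def test_absent_analyte_listed(self):
        m, ph = self._tiny()
        t = mdl.CoefficientTable(["met_099"], [1.0], ["none"], ["none"])
        with pytest.raises(mdl.ModelError, match="met_099"):
            mdl.apply_coefficient_table(m, ph, t)

    def test_cohort_missing_analyte_imputed(self):
        cfg = syn.default_config(n_cohorts=2, n_subjects=60, n_metabolites=5,
                                 seed=6, missing_analytes={"C01": [0]})
        m, ph, _ = syn.generate(cfg)
        t = mdl.CoefficientTable(["met_001", "met_002"], [1.0, 1.0],
                                 ["none", "none"], ["none", "none"])
        s = mdl.apply_coefficient_table(m, ph, t)
        assert np.isfinite(s).all()
        with pytest.raises(mdl.ModelError, match="imputation disabled"):
            mdl.apply_coefficient_table(m, ph, t, impute_missing=False)


class TestPredictAge:
    def test_training_data_reproduces_fitted_values(self, rng):
        X = _frame(rng.normal(size=(200, 4)))
        age = 50 + X["met_001"] + rng.normal(0, 1, 200)
        m = mdl.fit_elastic_net_age(X, age, seed=1)
        p1 = mdl.predict_age(m, X)
        p2 = mdl.predict_age(m, X)
        assert np.array_equal(p1, p2)

    def test_json_roundtrip_scores_stable(self, rng):
        X = _frame(rng.normal(size=(300, 4)))
        age = 50 + 2 * X["met_002"] - X["met_003"] + rng.normal(0, 1, 300)
        for fit in (lambda: mdl.fit_elastic_net_age(X, age, seed=1),
                    lambda: mdl.fit_mars_age(X, age, max_terms=9)):
            m = fit()
            clone = mdl.AgingModel.from_json(m.to_json())
            assert np.max(np.abs(mdl.predict_age(clone, X)
                                 - mdl.predict_age(m, X))) < 1e-12

    def test_schema_mismatch_errors(self, rng):
        X = _frame(rng.normal(size=(100, 3)))
        age = 50 + X["met_001"] + rng.normal(0, 1, 100)
        m = mdl.fit_elastic_net_age(X, age, seed=0)
        with pytest.raises(mdl.ModelError, match="met_003"):
            mdl.predict_age(m, X[["met_001", "met_002"]])
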