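import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor

from metaboage import preprocess as pp
from metaboage import synthetic as syn


def _matrix_from_array(X, cohort="A"):
    n, p = X.shape
    df = pd.DataFrame(X, columns=[f"met_{j + 1:03d}" for j in range(p)])
    df.insert(0, "visit", 1)
    df.insert(0, "cohort", cohort)
    df.insert(0, "subject_id", [f"s{i}" for i in range(n)])
    df.insert(0, "sample_id", [f"s{i}_v1" for i in range(n)])
    return df


class TestFilterVariables:
    def test_identical_replicates_no_corr_exclusions(self, small_dataset):
        _, matrix, _, _ = small_dataset
        rep = pp.filter_variables(matrix, replicate_matrix=matrix.copy())
        assert rep.excluded_replicate_corr == {}

    def test_cohort_absent_analyte_excluded(self):
        cfg = syn.default_config(n_cohorts=2, n_subjects=50, n_metabolites=6,
                                 seed=1, missing_analytes={"C01": [0]})
        m, _, _ = syn.generate(cfg)
        rep = pp.filter_variables(m)
        assert "met_001" in rep.excluded_missing
        assert "met_001" not in rep.retained_analytes

    def test_low_replicate_correlation_excluded(self, rng):
        X = rng.normal(size=(500, 3))
        m = _matrix_from_array(X)
        repm = m.copy()
        # noise calibrated so a direct Pearson oracle lands near r = 0.5
        noisy = X[:, 1] + rng.normal(0, np.sqrt(3) * X[:, 1].std(), 500)
        repm["met_002"] = noisy
        r_oracle = np.corrcoef(X[:, 1], noisy)[0, 1]
        assert r_oracle < 0.7
        rep = pp.filter_variables(m, replicate_matrix=repm, r_threshold=0.7)
        assert "met_002" in rep.excluded_replicate_corr
        assert rep.excluded_replicate_corr["met_002"] == pytest.approx(r_oracle)

    def test_dispositions_partition_analytes(self, small_dataset):
        _, matrix, _, _ = small_dataset
        rep = pp.filter_variables(matrix)
        analytes = syn.analyte_columns(matrix)
        claimed = (set(rep.excluded_missing) | set(rep.excluded_replicate_corr)
                   | set(rep.retained_analytes))
        assert claimed == set(analytes)
        assert not set(rep.retained_analytes) & set(rep.excluded_missing)

    def test_all_excluded_raises(self, rng):
        X = rng.normal(size=(30, 2))
        m1 = _matrix_from_array(X, cohort="A")
        m2 = _matrix_from_array(np.full((30, 2), np.nan), cohort="B")
        m2["sample_id"] = [f"b{i}" for i in range(30)]
        m = pd.concat([m1, m2], ignore_index=True)
        with pytest.raises(pp.QCError):
            pp.filter_variables(m)


class TestDetectOutliers:
    def test_injected_point_flagged(self, rng):
        X = rng.normal(size=(200, 10))
        med = np.median(X, axis=0)
        mad = np.median(np.abs(X - med), axis=0) * 1.4826
        X[0] = med + 10 * mad  # 10 robust SDs along every coordinate
        m = _matrix_from_array(X)
        # oracle: that point has the largest robust Mahalanobis-type distance
        d = np.sum(((X - med) / mad) ** 2, axis=1)
        assert np.argmax(d) == 0
        rep = pp.detect_outliers(m)
        assert "s0_v1" in rep.outlier_samples

    def test_zero_threshold_removes_nothing(self, rng):
        X = rng.normal(size=(100, 5))
        X[0] += 50
        rep = pp.detect_outliers(_matrix_from_array(X), weight_threshold=0.0)
        assert rep.outlier_samples == {}

    def test_deterministic_on_duplicate_input(self, small_dataset):
        _, matrix, _, _ = small_dataset
        r1 = pp.detect_outliers(matrix)
        r2 = pp.detect_outliers(matrix.copy())
        assert r1.outlier_samples == r2.outlier_samples

    def test_weights_in_unit_interval(self, rng):
        X = rng.normal(size=(150, 8))
        X[:5] += 20
        w = pp._cohort_outlier_weights(X)
        assert np.all((w >= 0) & (w <= 1))

    def test_sensitivity_on_injected_synthetic_outliers(self):
        hits = total = 0
        for seed in range(20):
            cfg = syn.default_config(n_cohorts=2, n_subjects=150,
                                     n_metabolites=15, seed=seed,
                                     outlier_fraction=0.02)
            m, _, truth = syn.generate(cfg)
            rep = pp.detect_outliers(m)
            inj = set(truth.outlier_samples)
            hits += len(inj & set(rep.outlier_samples))
            total += len(inj)
        assert hits / total >= 0.95

    def test_small_cohort_rejected(self, rng):
        m = _matrix_from_array(rng.normal(size=(10, 3)))
        with pytest.raises(pp.QCError, match="fewer than 20"):
            pp.detect_outliers(m)


class TestCalibration:
    def _paired(self, rng, factor=2.0):
        n, p = 300, 4
        X = rng.normal(10, 1, size=(n, p))
        ref = _matrix_from_array(X, cohort="REF")
        tgt = _matrix_from_array(X * factor, cohort="TGT")
        tgt["sample_id"] = [f"t{i}" for i in range(n)]
        tgt["subject_id"] = [f"t{i}" for i in range(n)]
        matrix = pd.concat([ref, tgt], ignore_index=True)
        pheno = pd.DataFrame({
            "sample_id": matrix["sample_id"],
            "cohort": matrix["cohort"],
            "age": np.tile(rng.uniform(40, 60, n), 2),
            "sex": np.tile(rng.integers(0, 2, n), 2),
            "bmi": np.tile(rng.normal(27, 3, n), 2),
            "ethnicity": "EUR",
        })
        return matrix, pheno

    def test_doubled_target_recovers_half(self, rng):
        matrix, pheno = self._paired(rng, factor=2.0)
        cal, cf = pp.calibrate_cohorts(matrix, pheno, "REF")
        assert np.allclose(cf.factors.loc["TGT"], 0.5, atol=0.02)
        analytes = syn.analyte_columns(matrix)
        med_ref = cal[cal["cohort"] == "REF"][analytes].median()
        med_tgt = cal[cal["cohort"] == "TGT"][analytes].median()
        assert np.allclose(med_tgt / med_ref, 1.0, atol=0.02)

    def test_identical_target_gives_exact_unit_factors(self, rng):
        matrix, pheno = self._paired(rng, factor=1.0)
        _, cf = pp.calibrate_cohorts(matrix, pheno, "REF")
        assert (cf.factors.loc["TGT"] == 1.0).all()
        assert (cf.factors.loc["REF"] == 1.0).all()

    def test_calibration_idempotent(self, small_dataset):
        _, matrix, pheno, _ = small_dataset
        cal, _ = pp.calibrate_cohorts(matrix, pheno, "C02")
        _, cf2 = pp.calibrate_cohorts(cal, pheno, "C02")
        assert np.all(np.abs(cf2.factors.to_numpy() - 1.0) < 0.01)

    def test_near_noop_without_batch_effects(self, clean_dataset):
        _, matrix, pheno, _ = clean_dataset
        _, cf = pp.calibrate_cohorts(matrix, pheno, "C02")
        assert np.median(np.abs(cf.factors.to_numpy() - 1.0)) < 0.02

    def test_missing_reference_cohort_raises(self, small_dataset):
        _, matrix, pheno, _ = small_dataset
        with pytest.raises(pp.CalibrationError, match="not present"):
            pp.calibrate_cohorts(matrix, pheno, "NOPE")

    def test_disjoint_strata_raise_with_cohort_name(self, rng):
        ref = _matrix_from_array(rng.normal(size=(50, 3)), cohort="REF")
        tgt = _matrix_from_array(rng.normal(size=(50, 3)), cohort="TGT")
        tgt["sample_id"] = [f"t{i}" for i in range(50)]
        matrix = pd.concat([ref, tgt], ignore_index=True)
        pheno = pd.DataFrame({
            "sample_id": matrix["sample_id"], "cohort": matrix["cohort"],
            "age": np.r_[np.full(50, 30.0), np.full(50, 80.0)],
            "sex": 1, "bmi": 27.0, "ethnicity": "EUR",
        })
        with pytest.raises(pp.CalibrationError, match="TGT"):
            pp.calibrate_cohorts(matrix, pheno, "REF")


class TestKnnImpute:
    def test_no_missing_identity(self, rng):
        m = _matrix_from_array(rng.normal(size=(40, 4)))
        out = pp.knn_impute(m)
        pd.testing.assert_frame_equal(out, m)

    def test_k_equals_n_minus_one_gives_global_mean(self, rng):
        X = rng.normal(size=(30, 3))
        m = _matrix_from_array(X)
        m.loc[0, "met_002"] = np.nan
        out = pp.knn_impute(m, k=29)
        assert out.loc[0, "met_002"] == pytest.approx(X[1:, 1].mean())

    def test_cluster_imputation_matches_bruteforce(self, rng):
        a = rng.normal(0, 0.3, size=(25, 3))
        b = rng.normal(8, 0.3, size=(25, 3))
        X = np.vstack([a, b])
        m = _matrix_from_array(X)
        m.loc[0, "met_003"] = np.nan
        out = pp.knn_impute(m, k=5)
        # brute-force oracle in the standardized complete-column space
        comp = X[:, :2]
        mu, sd = comp.mean(0), comp.std(0)
        Z = (comp - mu) / sd
        d = np.linalg.norm(Z - Z[0], axis=1)
        d[0] = np.inf
        nn = np.argsort(d)[:5]
        assert out.loc[0, "met_003"] == pytest.approx(X[nn, 2].mean())
        assert a[:, 2].min() - 1 < out.loc[0, "met_003"] < a[:, 2].max() + 1

    def test_observed_entries_untouched(self, rng):
        X = rng.normal(size=(30, 3))
        m = _matrix_from_array(X)
        m.loc[3, "met_001"] = np.nan
        out = pp.knn_impute(m, k=4)
        mask = m["met_001"].notna()
        assert (out.loc[mask, "met_001"] == m.loc[mask, "met_001"]).all()

    def test_all_missing_analyte_raises(self, rng):
        m = _matrix_from_array(rng.normal(size=(25, 3)))
        m["met_002"] = np.nan
        with pytest.raises(pp.ImputationError):
            pp.knn_impute(m)

    def test_row_permutation_commutes(self, rng):
        X = rng.normal(size=(40, 4))
        m = _matrix_from_array(X)
        m.loc[2, "met_001"] = np.nan
        out1 = pp.knn_impute(m, k=6)
        perm = rng.permutation(len(m))
        m_perm = m.iloc[perm].reset_index(drop=True)
        out2 = pp.knn_impute(m_perm, k=6)
        merged = out2.set_index("sample_id").loc[out1["sample_id"]]
        assert np.allclose(merged[syn.analyte_columns(m)].to_numpy(),
                           out1[syn.analyte_columns(m)].to_numpy())


class TestVifPrune:
    def test_orthogonal_analytes_all_retained(self):
        n = 300
        t = np.arange(n)
        X = np.column_stack([np.sin(2 * np.pi * t / n * k) for k in (1, 2, 3)])
        trace = pp.vif_prune(_matrix_from_array(X))
        assert trace.removal_order == []
        assert len(trace.retained) == 3

    def test_exact_collinearity_removed_first_with_inf_vif(self, rng):
        x1, x2 = rng.normal(size=(2, 200))
        X = np.column_stack([x1, x2, x1 + x2])
        trace = pp.vif_prune(_matrix_from_array(X))
        name, vif = trace.removal_order[0]
        assert vif == np.inf or vif > 1e8
        assert len(trace.retained) == 2

    def test_factor_model_final_set_below_threshold_bruteforce(self, rng):
        # 10 analytes from a latent-factor model; verify against statsmodels VIF
        F = rng.normal(size=(500, 3))
        L = rng.normal(size=(3, 10))
        X = F @ L + 0.3 * rng.normal(size=(500, 10))
        m = _matrix_from_array(X)
        trace = pp.vif_prune(m, threshold=5.0)
        Xr = m[trace.retained].to_numpy()
        Xr = np.column_stack([np.ones(len(Xr)), Xr])
        vifs = [variance_inflation_factor(Xr, j + 1) for j in range(len(trace.retained))]
        assert max(vifs) < 5.0

    def test_removal_vifs_exceed_threshold(self, small_dataset):
        _, matrix, _, _ = small_dataset
        trace = pp.vif_prune(matrix[matrix["visit"] == 1], threshold=5.0)
        for _, v in trace.removal_order:
            assert v >= 5.0
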