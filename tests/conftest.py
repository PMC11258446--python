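import numpy as np
import pytest

from metaboage import synthetic as syn


@pytest.fixture(scope="session")
def small_dataset():
    """4 cohorts x 200 subjects, 20 analytes, batch effects + survival."""
    cfg = syn.default_config(
        n_cohorts=4, n_subjects=200, n_metabolites=20, seed=11,
        batch_sd=0.1, repeat_visit_fraction=0.1,
    )
    matrix, pheno, truth = syn.generate(cfg)
    pheno = syn.simulate_survival(pheno, matrix, cfg)
    matrix, pheno = syn.add_longitudinal_visits(matrix, pheno, cfg, truth)
    return cfg, matrix, pheno, truth


@pytest.fixture(scope="session")
def clean_dataset():
    """No batch effects, no outliers, no missingness: calibration near-no-op."""
    cfg = syn.default_config(n_cohorts=3, n_subjects=300, n_metabolites=15, seed=5)
    matrix, pheno, truth = syn.generate(cfg)
    pheno = syn.simulate_survival(pheno, matrix, cfg)
    return cfg, matrix, pheno, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
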