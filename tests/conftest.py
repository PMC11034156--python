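import numpy as np
import pandas as pd
import pytest

import combatstab as cs
from combatstab.data import COVARIATE_COLUMNS


@pytest.fixture(scope="session")
def silver():
    """Default matched silver-standard cohort with its ground truth."""
    config = cs.CohortConfig(seed=123)
    return cs.generate_matched_cohort(config)


@pytest.fixture(scope="session")
def silver_fit(silver):
    """ComBat fit + age regression of the silver cohort."""
    table, _ = silver
    harmonized, fit = cs.harmonize(table)
    reg = cs.fit_feature_regressions(harmonized, "combat_ols")
    return fit, reg


def make_table(n1=8, n2=8, n_features=3, seed=0, values=None,
               site_names=("site1", "site2"), ages=None):
    """Hand-rolled tiny FeatureTable for unit tests."""
    rng = np.random.default_rng(seed)
    n = n1 + n2
    if ages is None:
        ages = rng.uniform(60, 90, size=n)
    cov = pd.DataFrame({
        "participant_id": [f"p{i:03d}" for i in range(n)],
        "site": [site_names[0]] * n1 + [site_names[1]] * n2,
        "age": ages,
        "sex": rng.integers(0, 2, size=n),
        "diagnosis": rng.integers(0, 2, size=n),
        "race": rng.choice(["nonhispanic_white", "other"], size=n),
        "education": rng.normal(16, 2, size=n),
        "apoe2": rng.integers(0, 2, size=n),
        "apoe4": rng.integers(0, 2, size=n),
    })
    assert list(cov.columns) == COVARIATE_COLUMNS
    if values is None:
        values = rng.normal(0.5, 0.05, size=(n, n_features))
    return cs.FeatureTable(covariates=cov, values=np.asarray(values, float))
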