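"""Shared fixtures: cohorts at two scales and compact model parameters."""

import numpy as np
import pandas as pd
import pytest

import t2drisk as t

TINY_PARAMS = {"n_estimators": 25, "max_depth": 3}


@pytest.fixture(scope="session")
def default_config():
    return t.CohortConfig(seed=7)


@pytest.fixture(scope="session")
def default_bundle(default_config):
    """Full-size cohort with missingness, augmentation and engineering."""
    bundle = t.generate_cohort(default_config)
    bundle = t.inject_missingness(bundle, default_config)
    bundle = t.augment_cohort_geospatial(bundle)
    return t.engineer_features(bundle)


@pytest.fixture(scope="session")
def raw_default_bundle(default_config):
    """Full-size cohort before any downstream processing."""
    return t.generate_cohort(default_config)


@pytest.fixture(scope="session")
def smoke_config():
    return t.CohortConfig.smoke(seed=3)


@pytest.fixture(scope="session")
def smoke_bundle(smoke_config):
    bundle = t.generate_cohort(smoke_config)
    return t.inject_missingness(bundle, smoke_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_classification(rng):
    """One strong driver, one pure-noise feature, grouped individuals."""
    n = 400
    driver = rng.normal(size=n)
    y = (driver + 0.3 * rng.normal(size=n) > 0).astype(int)
    X = pd.DataFrame({"driver": driver, "noise": rng.normal(size=n)})
    groups = rng.integers(0, 20, n)
    return X, y, groups
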