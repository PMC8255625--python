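import warnings
from dataclasses import replace

import pytest

from mpmri import (
    CohortConfig,
    calibrate_residual_correlation,
    feature_table,
    generate_cohort,
    load_reference_params,
)


@pytest.fixture(scope="session")
def specs():
    return load_reference_params()


@pytest.fixture(scope="session")
def calibrated_config(specs):
    """Default cohort config with the residual correlation calibrated
    against the published pooled correlations (shared across tests; the
    T1-MTR pair is known-infeasible and warns)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = calibrate_residual_correlation(CohortConfig(seed=20240601))
    return result.config


@pytest.fixture(scope="session")
def default_cohort(specs, calibrated_config):
    """The study-sized cohort: 5 subjects, anatomical VOI sizes,
    calibrated cross-contrast coupling, fixed seed."""
    cfg = replace(calibrated_config, seed=11)
    return generate_cohort(cfg, specs)


@pytest.fixture(scope="session")
def cohort_features(specs, default_cohort):
    return feature_table(default_cohort, specs)
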