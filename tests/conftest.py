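import numpy as np
import pytest

from aerolus.pipeline import build_ct_table, build_feature_table, merge_analysis_table
from aerolus.simulate import (
    PressureSchedule,
    SimulationConfig,
    generate_cohort,
    observations_to_frame,
)

COHORT_SEED = 1


@pytest.fixture(scope="session")
def desk_config() -> SimulationConfig:
    return SimulationConfig.desk_scale()


@pytest.fixture(scope="session")
def cohort(desk_config):
    """Seven-lamb default-schedule cohort shared across the suite."""
    return generate_cohort(7, PressureSchedule.default(), desk_config, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def analysis_table(desk_config, cohort):
    """Merged manifest + features + CT table for the shared cohort."""
    manifest = observations_to_frame(cohort)
    features = build_feature_table(cohort, desk_config)
    ct = build_ct_table(cohort)
    return merge_analysis_table(manifest, features, ct)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
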