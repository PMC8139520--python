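import numpy as np
import pandas as pd
import pytest

from pseudocohort import PipelineConfig, run_pipeline, scenarios
from pseudocohort.simulate import CohortProcess


@pytest.fixture(scope="session")
def geometric_process():
    """Constant initiation hazard 0.1 over ages 15-24, nothing else."""
    return CohortProcess(
        birth_years=(1950, 1950),
        sex="M",
        initiation_hazard=[(15, 24, 0.1)],
    )


@pytest.fixture
def six_record_cell():
    """One (cohort, sex, survey) cell with hand-checkable proportions."""
    return pd.DataFrame(
        {
            "survey_id": "S1",
            "survey_year": 2000,
            "sex": "M",
            "age": [41, 42, 43, 44, 45, 46],  # births 1954-1959: one cohort
            "smoking_status": ["current", "current", "never", "never", "never", "former"],
            "initiation_age": np.nan,
            "base_weight": 1.0,
            "weight": 1.0,
            "has_former_question": True,
            "has_initiation_age": False,
        }
    )


@pytest.fixture(scope="session")
def small_scenario():
    """Scaled-down default study: same design, ~1/12 of the sampling."""
    return scenarios.default_scenario(n_per_cohort_year=260, survey_scale=0.085)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_scenario):
    """One scaled pipeline run shared by the fast integration tests."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(out_dir=str(out), scenario=small_scenario, min_n=50)
    run_pipeline(cfg)
    return out


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """The default-scale study used for end-to-end parameter recovery."""
    out = tmp_path_factory.mktemp("pipeline_full") / "run"
    cfg = PipelineConfig(out_dir=str(out))
    run_pipeline(cfg)
    return out
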