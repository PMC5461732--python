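import numpy as np
import pytest

from practice_futi import CohortModel, MonitorConfig, TrialDesign


@pytest.fixture(scope="session")
def cohort_model() -> CohortModel:
    return CohortModel()


@pytest.fixture(scope="session")
def trial_design() -> TrialDesign:
    return TrialDesign()


@pytest.fixture(scope="session")
def monitor_config() -> MonitorConfig:
    return MonitorConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


@pytest.fixture
def patients_csv(tmp_path):
    """Small well-formed patient file using the pre-dichotomized flag schema."""
    path = tmp_path / "patients.csv"
    path.write_text(
        "patient_id,age,sex,nursing_home,malignancy,chf,cvd,cirrhosis,"
        "renal_disease,altered_mental_status,rr_ge_30,sbp_lt_90,pulse_ge_125,temp_ge_40\n"
        "p1,18,F,0,0,0,0,0,0,0,0,0,0,0\n"
        "p2,80,M,1,1,0,0,0,0,1,0,0,0,0\n"
        "p3,60,F,0,0,0,0,0,0,0,0,0,1,1\n"
    )
    return path
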