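import pandas as pd
import pytest

from markerpair import Cohort, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort300():
    """Mid-sized cohort with both outcomes, two informative markers, 3 decoys."""
    return simulate_cohort(SimConfig(n=300, seed=7, n_decoy=3))


@pytest.fixture(scope="session")
def cohort_response_only(cohort300):
    df = cohort300.data.drop(columns=["surv_time", "surv_event"])
    return Cohort(df, cohort300.markers, cohort300.covariates,
                  has_response=True, has_survival=False)


@pytest.fixture(scope="session")
def cohort_survival_only(cohort300):
    df = cohort300.data.drop(columns=["response"])
    return Cohort(df, cohort300.markers, cohort300.covariates,
                  has_response=False, has_survival=True)


@pytest.fixture()
def tiny_csv(tmp_path):
    path = tmp_path / "tiny.csv"
    pd.DataFrame({
        "id": ["a", "b", "c"],
        "resp": ["R", "NR", "R"],
        "os_time": [5.0, 10.0, 2.5],
        "os_event": [1, 0, 1],
        "tmb": [12.0, 3.0, 8.0],
    }).to_csv(path, index=False)
    return path
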