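import numpy as np
import pandas as pd
import pytest

from alstrialsim import (TrialDataset, TrialDesign, default_parameters,
                         generate_trial)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def null_trial(params):
    """One 150/arm, 18-month trial with no treatment effect."""
    return generate_trial(params, TrialDesign(seed=20180319))


@pytest.fixture(scope="session")
def small_trial(params):
    """A fast 40/arm, 12-month trial for structural tests."""
    return generate_trial(params, TrialDesign(n_per_arm=40, max_followup=12.0,
                                              seed=7))


def make_dataset(records, survival):
    """Tiny hand-built dataset: records = (sid, arm, t, score) rows,
    survival = (sid, arm, time, status) rows."""
    long = pd.DataFrame(records,
                        columns=["subject_id", "arm", "time_months", "alsfrs_r"])
    long["visit_index"] = np.rint(long.time_months).astype(int)
    surv = pd.DataFrame(survival,
                        columns=["subject_id", "arm", "time_months", "status"])
    return TrialDataset(long, surv)


@pytest.fixture
def toy_builder():
    return make_dataset
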