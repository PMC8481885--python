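import numpy as np
import pandas as pd
import pytest

from amcen import LabeledMatrix, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic study (de_effect=2, dm_effect=0.2, planted_rho=0.8,
    20 planted triples) at a fixed seed; shared across tests."""
    return generate_dataset(SimConfig(seed=1))


def make_matrix(case_rows, control_rows, feature_ids=None):
    """Small LabeledMatrix from per-feature case/control value lists."""
    case_rows = np.atleast_2d(np.asarray(case_rows, dtype=float))
    control_rows = np.atleast_2d(np.asarray(control_rows, dtype=float))
    n_feat = case_rows.shape[0]
    if feature_ids is None:
        feature_ids = [f"F{i}" for i in range(n_feat)]
    samples = [f"c{i}" for i in range(case_rows.shape[1])] + \
              [f"k{i}" for i in range(control_rows.shape[1])]
    values = pd.DataFrame(np.hstack([case_rows, control_rows]),
                          index=feature_ids, columns=samples)
    groups = pd.Series(["case"] * case_rows.shape[1] + ["control"] * control_rows.shape[1],
                       index=samples)
    return LabeledMatrix(values, groups)
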