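import numpy as np
import pandas as pd
import pytest

from adrtriage.schema import PREDICTOR_COLUMNS, ReportTable
from adrtriage.simulate import SimulationConfig, simulate_reports


def make_table(X, y=None, **columns) -> ReportTable:
    """Build a valid ReportTable from a predictor matrix and optional labels.

    Unspecified metadata flags default to 0 and assessments to 3;
    serious_ade is kept consistent with the severity items.
    """
    X = np.atleast_2d(np.asarray(X, dtype=int))
    n, p = X.shape
    full = np.zeros((n, 11), dtype=int)
    full[:, :p] = X
    df = pd.DataFrame(full, columns=list(PREDICTOR_COLUMNS))
    df["new_ade"] = 0
    df["serious_ade"] = (full[:, 5:] == 1).any(axis=1).astype(int)
    df["gender"] = 0
    df["suspect"] = 0
    for c in ("r_assess", "ri_assess", "muni_assess", "prov_assess"):
        df[c] = 3
    if y is not None:
        df["label"] = np.asarray(y, dtype=int)
    for name, values in columns.items():
        df[name] = values
    return ReportTable(df)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(n=2000, seed=5)


@pytest.fixture(scope="session")
def sim_table(sim_config):
    return simulate_reports(sim_config)


@pytest.fixture(scope="session")
def fitted_model(sim_config, sim_table):
    from adrtriage.model import fit_model

    return fit_model(sim_table, sim_config.true_model.partition)
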