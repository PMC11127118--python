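import numpy as np
import pandas as pd
import pytest

from raicd import default_code_map, default_weight_table, demo_code_map
from raicd.synthetic import SimulationConfig, generate


@pytest.fixture(scope="session")
def cmap():
    return default_code_map()


@pytest.fixture(scope="session")
def demo_map():
    return demo_code_map()


@pytest.fixture(scope="session")
def wt():
    return default_weight_table()


@pytest.fixture(scope="session")
def small_sim(cmap):
    """A 5000-record synthetic dataset shared across tests (seed fixed)."""
    records, truth = generate(SimulationConfig(n=5000, seed=7), cmap)
    return records, truth


def make_records(rows):
    """Build a standardized records frame from (age, sex, dx, disp, ...) dicts."""
    defaults = dict(
        sex="female", dx_codes=(), disposition="routine", survey_weight=1.0,
        cluster_id=None, operative=True, elective=np.nan,
        length_of_stay=np.nan, charges=np.nan,
    )
    out = []
    for i, row in enumerate(rows):
        r = {"record_id": f"r{i}", **defaults, **row}
        out.append(r)
    df = pd.DataFrame(out)
    df["sex"] = df["sex"].astype("string")
    df["disposition"] = df["disposition"].astype("string")
    return df
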