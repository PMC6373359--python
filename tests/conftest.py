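import numpy as np
import pandas as pd
import pytest

from cvdmmi.dose_response import DoseResponseSpec
from cvdmmi.grouped_data import GroupedTable, REQUIRED_COLUMNS
from cvdmmi.hazard_model import BaselineParams, HazardModel
from cvdmmi.synthetic_cohort import generate, preset


def make_table(rows, endpoint="cevd"):
    """Build a GroupedTable from (city, sex, pyr, mean_agex, mean_age,
    mean_dose, cases) tuples; category labels are synthesized."""
    recs = []
    for i, (city, sex, pyr, agex, age, dose, cases) in enumerate(rows):
        recs.append((city, sex, f"e{i}", f"a{i}", "p0", f"d{i}",
                     max(int(pyr // 40), 1), pyr, agex, age, dose, cases, cases))
    df = pd.DataFrame(recs, columns=list(REQUIRED_COLUMNS))
    return GroupedTable(df, endpoint=endpoint)


@pytest.fixture
def small_table():
    return make_table([
        ("hiroshima", "male", 1000.0, 20.0, 50.0, 0.0, 12),
        ("hiroshima", "female", 1500.0, 25.0, 60.0, 0.1, 20),
        ("nagasaki", "male", 800.0, 30.0, 70.0, 1.0, 15),
        ("nagasaki", "female", 900.0, 35.0, 80.0, 2.5, 25),
    ])


@pytest.fixture(scope="session")
def cevd_table():
    """One seeded LSS-like cohort under linear no-threshold truth."""
    table, truth = generate(preset("cevd_like"), seed=0)
    return table, truth


@pytest.fixture(scope="session")
def lnt_template():
    """ERR-LNT template with the generator's baseline structure, default
    (uninformed) parameter values."""
    sc = preset("cevd_like")
    return HazardModel(
        transfer="ERR",
        baseline=BaselineParams(values={}, active=sc.truth.baseline.active),
        dose_response=DoseResponseSpec.default("lnt"),
    )
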