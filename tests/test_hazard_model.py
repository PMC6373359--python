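import numpy as np
import pytest

from cvdmmi.dose_response import DoseResponseSpec
from cvdmmi.hazard_model import (BaselineParams, CellArrays, DemParams,
                                 HazardModel, HazardPositivityError,
                                 baseline_hazard, dem_factor, expected_cases,
                                 total_hazard)
from cvdmmi.synthetic_cohort import generate, preset

from conftest import make_table


def _cell(pyr=1000.0, age=70.0, agex=30.0, dose=1.0, sex="male", city="hiroshima"):
    return make_table([(city, sex, pyr, agex, age, dose, 0)])


def test_intercept_only_baseline_is_constant():
    bl = BaselineParams(values={"intercept": -5.0}, active=("intercept",))
    for age, agex in [(50.0, 10.0), (70.0, 30.0), (85.0, 55.0)]:
        h = baseline_hazard(bl, CellArrays.from_table(_cell(age=age, agex=agex)))
        assert h[0] == pytest.approx(np.exp(-5.0))


def test_baseline_log_linearity_in_age():
    k = 3.0
    bl = BaselineParams(values={"intercept": -5.0, "log_age": k},
                        active=("intercept", "log_age"))
    h1 = baseline_hazard(bl, CellArrays.from_table(_cell(age=40.0, agex=10.0)))[0]
    h2 = baseline_hazard(bl, CellArrays.from_table(_cell(age=80.0, agex=10.0)))[0]
    assert h2 / h1 == pytest.approx(2.0**k)


def test_inactive_terms_contribute_nothing():
    bl = BaselineParams(values={"intercept": -5.0, "sex": 9.9}, active=("intercept",))
    h = baseline_hazard(bl, CellArrays.from_table(_cell(sex="female")))
    assert h[0] == pytest.approx(np.exp(-5.0))


def test_total_hazard_err_and_ear_arithmetic():
    bl = BaselineParams(values={"intercept": np.log(0.01)}, active=("intercept",))
    cells = CellArrays.from_table(_cell(dose=1.0))
    err = HazardModel("ERR", bl, DoseResponseSpec("lnt", {"beta": 0.5}))
    assert total_hazard(err, cells)[0] == pytest.approx(0.015)
    ear = HazardModel("EAR", bl, DoseResponseSpec("lnt", {"beta": 0.002}),
                      dems=DemParams(values={"sex": np.log(2.0)}, active=("sex",)))
    cells_f = CellArrays.from_table(_cell(dose=1.0, sex="female"))
    assert total_hazard(ear, cells_f)[0] == pytest.approx(0.01 + 0.002 * 2.0)


def test_total_hazard_equals_baseline_at_zero_dose():
    bl = BaselineParams(values={"intercept": -4.0, "sex": -0.3},
                        active=("intercept", "sex"))
    for family, params in [("lnt", {"beta": 0.7}),
                           ("two_line_spline", {"beta1": -1.0, "dth": 0.3, "beta2": 1.0})]:
        m = HazardModel("ERR", bl, DoseResponseSpec(family, params))
        cells = CellArrays.from_table(_cell(dose=0.0, sex="female"))
        assert total_hazard(m, cells)[0] == pytest.approx(
            baseline_hazard(bl, cells)[0])


def test_err_positivity_violation_flagged():
    bl = BaselineParams(values={"intercept": -4.0}, active=("intercept",))
    m = HazardModel("ERR", bl, DoseResponseSpec("two_line_spline",
                                                {"beta1": -2.0, "dth": 1.0, "beta2": 0.0}))
    cells = CellArrays.from_table(_cell(dose=1.0))
    with pytest.raises(HazardPositivityError):
        total_hazard(m, cells)
    assert total_hazard(m, cells, strict=False)[0] < 0


def test_err_ear_transfer_identity():
    """EAR = h0 * ERR: matched parameters give identical total hazards."""
    bl = BaselineParams(values={"intercept": np.log(0.02)}, active=("intercept",))
    cells = CellArrays.from_table(_cell(dose=2.0))
    err = HazardModel("ERR", bl, DoseResponseSpec("lnt", {"beta": 0.25}))
    ear = HazardModel("EAR", bl, DoseResponseSpec("lnt", {"beta": 0.25 * 0.02}))
    assert total_hazard(err, cells)[0] == pytest.approx(total_hazard(ear, cells)[0])


def test_dem_factor_all_inactive_is_one():
    cells = CellArrays.from_table(_cell(sex="female", age=50.0))
    assert dem_factor(DemParams(), cells)[0] == 1.0


def test_expected_cases_arithmetic_and_zero_py():
    bl = BaselineParams(values={"intercept": np.log(0.01)}, active=("intercept",))
    m = HazardModel("ERR", bl, DoseResponseSpec("lnt", {"beta": 0.0}))
    assert expected_cases(m, CellArrays.from_table(_cell(pyr=1000.0)))[0] == pytest.approx(10.0)
    assert expected_cases(m, CellArrays.from_table(_cell(pyr=0.0)))[0] == 0.0


def test_expected_total_matches_generator_bookkeeping():
    sc = preset("cevd_like", scale=0.2)
    table, truth = generate(sc, seed=11)
    # rebuild the calibrated truth model from the recorded parameters
    tp = truth["truth_params"]
    model = HazardModel(
        transfer=truth["transfer"],
        baseline=BaselineParams(values=tp["baseline"], active=tuple(tp["baseline"])),
        dose_response=DoseResponseSpec(truth["family"], tp["dose_response"]),
    )
    E = expected_cases(model, CellArrays.from_table(table))
    np.testing.assert_allclose(E, truth["expected_cells"], rtol=1e-10)
    assert E.sum() == pytest.approx(truth["expected_total"])
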