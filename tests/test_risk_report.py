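import numpy as np
import pandas as pd
import pytest

from cvdmmi.dose_response import DoseResponseSpec
from cvdmmi.fitting import FittedModel, fit_mle
from cvdmmi.hazard_model import BaselineParams, HazardModel
from cvdmmi.risk_report import (DEFAULT_EXCESS_BINS, excess_cases,
                                fit_categorical, kfold_stability,
                                mmi_excess_cases)
from cvdmmi.synthetic_cohort import generate, preset

from conftest import make_table


def _fit_like(model):
    return FittedModel(model=model, param_names=[], mle=np.array([]),
                       cov=np.zeros((0, 0)), deviance=0.0, npar=1, converged=True)


def test_excess_cases_zero_slope_and_arithmetic():
    bl = BaselineParams(values={"intercept": np.log(0.01)}, active=("intercept",))
    table = make_table([("hiroshima", "male", 1000.0, 30.0, 70.0, 0.7, 12)])
    zero = _fit_like(HazardModel("ERR", bl, DoseResponseSpec("lnt", {"beta": 0.0})))
    assert excess_cases(zero, table)["excess_cases"].sum() == 0.0
    half = _fit_like(HazardModel("ERR", bl, DoseResponseSpec("lnt", {"beta": 0.5 / 0.7})))
    df = excess_cases(half, table)
    # one cell, h0=0.01, ERR=0.5, PY=1000 -> 5 excess cases in the 0.5-1 Gy bin
    assert df.loc[df["bin"] == "0.5-1 Gy", "excess_cases"].item() == pytest.approx(5.0)
    assert df["excess_cases"].sum() == pytest.approx(5.0)


def test_excess_cases_requires_covering_bins():
    bl = BaselineParams(values={"intercept": -5.0}, active=("intercept",))
    table = make_table([("hiroshima", "male", 1000.0, 30.0, 70.0, 3.5, 1)])
    fit = _fit_like(HazardModel("ERR", bl, DoseResponseSpec("lnt", {"beta": 0.1})))
    with pytest.raises(ValueError, match="bins"):
        excess_cases(fit, table, bin_edges=(0.0, 1.0, 2.0))


def test_mmi_excess_table_consistency():
    """Sum row equals column sums and the MMI column is the weight-linear
    combination of the per-model columns, to 1e-9."""
    rng = np.random.default_rng(8)
    bins = [f"b{i}" for i in range(11)]
    tables = [pd.DataFrame({"bin": bins, "excess_cases": rng.normal(size=11)})
              for _ in range(3)]
    w = np.array([0.2, 0.5, 0.3])
    out = mmi_excess_cases(w, tables, model_names=["m1", "m2", "m3"])
    body = out.iloc[:-1]
    sums = out.iloc[-1]
    for c in ("m1", "m2", "m3", "MMI"):
        assert sums[c] == pytest.approx(body[c].sum(), abs=1e-9)
    expect = sum(wi * t["excess_cases"].to_numpy() for wi, t in zip(w, tables))
    np.testing.assert_allclose(body["MMI"].to_numpy(), expect, atol=1e-9)


def test_mmi_excess_single_model_is_identity():
    t = pd.DataFrame({"bin": ["a", "b"], "excess_cases": [1.5, -0.5]})
    out = mmi_excess_cases([1.0], [t], model_names=["m"])
    np.testing.assert_allclose(out["MMI"].iloc[:-1], t["excess_cases"])


def test_mmi_excess_misaligned_inputs_rejected():
    t = pd.DataFrame({"bin": ["a"], "excess_cases": [1.0]})
    t2 = pd.DataFrame({"bin": ["z"], "excess_cases": [1.0]})
    with pytest.raises(ValueError, match="align"):
        mmi_excess_cases([0.5, 0.5], [t])
    with pytest.raises(ValueError, match="identical"):
        mmi_excess_cases([0.5, 0.5], [t, t2], model_names=["a", "b"])


@pytest.fixture(scope="module")
def lnt_cohort():
    table, truth = generate(preset("cevd_like"), seed=0)
    bl = BaselineParams(values={}, active=preset("cevd_like").truth.baseline.active)
    return table, bl


def test_categorical_fit_reference_zero_and_monotone_trend(lnt_cohort):
    table, bl = lnt_cohort
    fit, levels = fit_categorical(table, baseline=bl)
    ref = levels[levels["reference"]]
    assert len(ref) == 1 and ref["level"].item() == 0.0 and np.isnan(ref["se"].item())
    est = levels.loc[~levels["reference"], "level"].to_numpy()
    # LNT truth: category estimates should rise with category mean dose
    assert est[-1] > est[0]
    assert np.all(np.isfinite(levels.loc[~levels["reference"], "se"]))


def test_kfold_stability_deterministic_and_reports_spread(lnt_cohort):
    table, bl = lnt_cohort
    tmpl = HazardModel("ERR", bl, DoseResponseSpec.default("lnt"))
    r1 = kfold_stability(tmpl, table, folds=(10,), seed=7)
    r2 = kfold_stability(tmpl, table, folds=(10,), seed=7)
    assert r1 == r2
    f = r1["folds"][10]
    assert f["n_refits"] == 10
    assert f["param_names"] == ["dr:beta"]
    assert len(f["mle_sd"]) == 1 and f["mle_sd"][0] > 0


def test_kfold_spread_shrinks_with_training_size(lnt_cohort):
    table, bl = lnt_cohort
    tmpl = HazardModel("ERR", bl, DoseResponseSpec.default("lnt"))
    r = kfold_stability(tmpl, table, folds=(5, 20), seed=3)
    # 20-fold training sets are larger than 5-fold ones: beta varies less
    assert r["folds"][20]["mle_sd"][0] < r["folds"][5]["mle_sd"][0]


def test_kfold_sparse_spline_reports_err_below_minus_one():
    table, _ = generate(preset("sparse"), seed=4)
    tmpl = HazardModel(
        "ERR",
        BaselineParams(values={}, active=("intercept", "sex", "log_age")),
        DoseResponseSpec.default("two_line_spline"),
    )
    r = kfold_stability(tmpl, table, folds=(8,), seed=4)
    f = r["folds"][8]
    assert f["n_err_below_neg1"] >= 1
    with pytest.raises(ValueError, match="folds"):
        kfold_stability(tmpl, table, folds=(10_000,), seed=0)
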