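import numpy as np
import pytest

from cvdmmi.dose_response import DoseResponseSpec, NESTED_EDGES
from cvdmmi.fitting import FittedModel, fit_mle
from cvdmmi.hazard_model import BaselineParams, DemParams, HazardModel
from cvdmmi.selection import (assemble_occams_group, compete_families,
                              gate_dems, streamline_baseline)
from cvdmmi.synthetic_cohort import generate, preset


def _full_template(transfer="ERR"):
    return HazardModel(transfer, BaselineParams(), DoseResponseSpec.default("lnt"))


@pytest.fixture(scope="module")
def streamlined():
    table, truth = generate(preset("cevd_like"), seed=0)
    bl, fit0, log = streamline_baseline(_full_template(), table)
    return table, truth, bl, fit0, log


def test_streamline_drops_null_city_keeps_real_terms(streamlined):
    """Truth has no city effect and no sex-age interaction; both should be
    eliminated while genuinely active terms survive."""
    table, truth, bl, fit0, log = streamlined
    assert "city" not in bl.active
    assert "sex_log_age" not in bl.active
    for term in ("sex", "log_age", "log_age_sq"):
        assert term in bl.active
    removed = [e["term"] for e in log.entries if e["stage"] == "streamline_remove"]
    assert set(removed) == set(BaselineParams().active) - set(bl.active)


def test_streamline_log_records_every_tested_term(streamlined):
    _, _, _, _, log = streamlined
    tested = [e for e in log.entries if e["stage"] == "streamline_test"]
    assert len(tested) >= len(BaselineParams().active) - 1
    assert all(np.isfinite(e["delta_dev"]) for e in tested)


def test_compete_lnt_truth_keeps_lnt_drops_lq(streamlined):
    table, truth, bl, _, _ = streamlined
    survivors, log = compete_families(bl, table, "ERR",
                                      families=("lnt", "q", "lq", "lth", "le"))
    assert "lnt" in survivors
    assert "lq" not in survivors  # extension not supported by LNT-truth data
    # survivors form an antichain of the nestedness graph
    for red, ext in NESTED_EDGES:
        assert not (red in survivors and ext in survivors)


def test_compete_spline_truth_spline_survives():
    table, _ = generate(preset("sparse", scale=20.0), seed=2)
    bl = BaselineParams(values={}, active=preset("sparse").truth.baseline.active)
    survivors, _ = compete_families(bl, table, "ERR",
                                    families=("lnt", "lth", "two_line_spline"))
    assert "two_line_spline" in survivors
    assert "lnt" not in survivors


def test_compete_zero_cases_collapses_to_baseline():
    table, _ = generate(preset("null_dose", scale=0.02), seed=1)
    df = table.data.copy()
    df["cases_cevd"] = 0.0
    from cvdmmi.grouped_data import GroupedTable
    table0 = GroupedTable(df, endpoint="cevd")
    bl = BaselineParams(values={}, active=("intercept",))
    survivors, _ = compete_families(bl, table0, "ERR", families=("lnt", "lq"))
    # with no cases no extension is ever significant: only the minimal
    # family survives, and the dose term buys no deviance over baseline alone
    assert set(survivors) == {"lnt"}
    base_only = fit_mle(
        HazardModel("ERR", bl, DoseResponseSpec("lnt", {"beta": 0.0})),
        table0, bounds={"dr:beta": (0.0, 0.0)})
    assert abs(survivors["lnt"].deviance - base_only.deviance) < 1e-3


def test_gate_dems_null_rejects_and_power_detects():
    # no DEM in truth: all three rejected on a seeded cohort
    table, _ = generate(preset("cevd_like"), seed=0)
    tmpl = HazardModel("ERR",
                       BaselineParams(values={}, active=preset("cevd_like").truth.baseline.active),
                       DoseResponseSpec.default("lnt"))
    fit = fit_mle(tmpl, table)
    gated, log = gate_dems(fit, table)
    assert gated.model.dems.active == ()

    # strong attained-age DEM in truth: retained
    table_h, _ = generate(preset("heart_like"), seed=0)
    tmpl_h = HazardModel("EAR",
                         BaselineParams(values={}, active=preset("heart_like").truth.baseline.active),
                         DoseResponseSpec.default("lnt"))
    fit_h = fit_mle(tmpl_h, table_h)
    gated_h, _ = gate_dems(fit_h, table_h)
    assert "attained_age" in gated_h.model.dems.active


def test_assemble_occams_group_weights_and_floor():
    table, _ = generate(preset("cevd_like"), seed=0)
    bl = BaselineParams(values={}, active=preset("cevd_like").truth.baseline.active)
    survivors, _ = compete_families(bl, table, "ERR", families=("lnt", "q"))
    named = {f"ERR-{k}": v for k, v in survivors.items()}
    group, _ = assemble_occams_group(named, n=int(table.cases.sum()))
    assert group.weights.sum() == pytest.approx(1.0)
    assert np.all(group.weights > 0)
    assert group.delta_ic.min() == 0.0

    single, _ = assemble_occams_group({"ERR-lnt": survivors["lnt"]})
    assert len(single) == 1 and single.weights[0] == pytest.approx(1.0)

    with pytest.raises(ValueError, match="empty"):
        assemble_occams_group({})


def test_selection_reproducible(streamlined):
    table, _, bl, _, _ = streamlined
    s1, log1 = compete_families(bl, table, "ERR", families=("lnt", "q", "lq"))
    s2, log2 = compete_families(bl, table, "ERR", families=("lnt", "q", "lq"))
    assert log1.to_records() == log2.to_records()
    assert sorted(s1) == sorted(s2)
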