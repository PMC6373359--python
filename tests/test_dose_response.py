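import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvdmmi.dose_response import (DoseResponseSpec, FAMILIES, NESTED_EDGES,
                                  NESTED_EMBEDDINGS, STEP_FIXED_W, evaluate,
                                  noael, zero_crossing)

DOSES = np.array([0.0, 0.01, 0.1, 0.3, 0.5, 1.0, 2.0, 3.5, 4.0])


@pytest.mark.parametrize("family, params, D, expected", [
    ("lnt", {"beta": 0.09}, 1.0, 0.09),
    ("lth", {"beta": 1.0, "dth": 0.5}, 0.3, 0.0),
    ("lth", {"beta": 1.0, "dth": 0.5}, 1.5, 1.0),
    ("q", {"beta": 0.05}, 2.0, 0.2),
    ("lq", {"beta1": 0.1, "beta2": 0.05}, 2.0, 0.4),
    ("le", {"beta": 0.2, "gamma": 0.0}, 1.5, 0.3),
    ("two_line_spline", {"beta1": -1.0, "dth": 0.2, "beta2": 1.0}, 0.4, 0.0),
    ("hormesis", {"c": -1.0, "beta": 2.0, "theta": 0.0}, 1.0, 1.0),
    ("hockey_stick", {"c": 0.0, "dth": 0.5, "beta": 1.0}, 1.5, 1.0),
])
def test_evaluate_closed_forms(family, params, D, expected):
    assert evaluate(DoseResponseSpec(family, params), D) == pytest.approx(expected)


def test_evaluate_vectorizes_and_rejects_negative_dose():
    spec = DoseResponseSpec("lnt", {"beta": 0.1})
    np.testing.assert_allclose(evaluate(spec, [0.0, 1.0, 2.0]), [0.0, 0.1, 0.2])
    with pytest.raises(ValueError):
        evaluate(spec, -0.1)


def test_unknown_family_and_invalid_params_rejected():
    with pytest.raises(ValueError, match="unknown"):
        DoseResponseSpec("spline9", {"beta": 1.0})
    with pytest.raises(ValueError, match="dth"):
        DoseResponseSpec("lth", {"beta": 1.0, "dth": -0.5})
    with pytest.raises(ValueError, match="missing"):
        DoseResponseSpec("lq", {"beta1": 0.1})


def _random_params(family, rng):
    out = {}
    for p in FAMILIES[family].params:
        lo, hi = p.bounds
        lo, hi = max(lo, -2.0), min(hi, 4.0)
        out[p.name] = float(rng.uniform(lo, hi))
    return out


@given(st.integers(0, 10_000))
@settings(max_examples=60, deadline=None)
def test_err_zero_at_zero_dose_for_all_families(seed):
    """err(0) = 0 for every family and any valid parameter draw."""
    rng = np.random.default_rng(seed)
    for family in FAMILIES:
        if family == "categorical":
            spec = DoseResponseSpec(
                "categorical", {"level_1": rng.normal(), "level_2": rng.normal()},
                category_edges=(0.005, 0.5))
        else:
            spec = DoseResponseSpec(family, _random_params(family, rng))
        assert evaluate(spec, 0.0) == 0.0


@given(st.integers(0, 10_000))
@settings(max_examples=40, deadline=None)
def test_nestedness_identities(seed):
    """Each nestedness edge's parameter restriction reproduces the reduced
    family exactly on a dose grid."""
    rng = np.random.default_rng(seed)
    for red, ext in NESTED_EDGES:
        p_red = _random_params(red, rng)
        spec_red = DoseResponseSpec(red, p_red)
        spec_ext = DoseResponseSpec(ext, NESTED_EMBEDDINGS[(red, ext)](p_red))
        if (red, ext) == ("lnt", "two_line_spline"):
            # embedding sets equal slopes; knee position is then irrelevant
            pass
        np.testing.assert_allclose(evaluate(spec_ext, DOSES), evaluate(spec_red, DOSES),
                                   atol=1e-12)


def test_smooth_step_monotone_bounded_and_limits_to_step():
    spec = DoseResponseSpec("smooth_step", {"A": 0.5, "dth": 1.0, "w": 0.3})
    d = np.linspace(0, 4, 200)
    v = evaluate(spec, d)
    assert np.all(np.diff(v) >= -1e-12)
    assert v.max() <= 0.5 + 1e-12
    sharp = DoseResponseSpec("smooth_step", {"A": 0.5, "dth": 1.0, "w": STEP_FIXED_W})
    step = DoseResponseSpec("step", {"A": 0.5, "dth": 1.0, "w": STEP_FIXED_W})
    np.testing.assert_allclose(evaluate(sharp, DOSES), evaluate(step, DOSES), atol=1e-12)


@given(st.floats(0.05, 3.95), st.floats(-2, 2), st.floats(-2, 2))
@settings(max_examples=60, deadline=None)
def test_two_line_spline_continuous_at_knee(dth, b1, b2):
    spec = DoseResponseSpec("two_line_spline", {"beta1": b1, "dth": dth, "beta2": b2})
    eps = 1e-9
    left, right = evaluate(spec, dth - eps), evaluate(spec, dth + eps)
    assert abs(left - right) < 1e-6


def test_zero_crossing_cases():
    dip = DoseResponseSpec("two_line_spline", {"beta1": -1.0, "dth": 0.2, "beta2": 1.0})
    assert zero_crossing(dip) == pytest.approx(0.4, abs=1e-5)
    lnt = DoseResponseSpec("lnt", {"beta": 0.1})
    assert zero_crossing(lnt) is None
    lth = DoseResponseSpec("lth", {"beta": 1.0, "dth": 0.5})
    assert zero_crossing(lth) is None  # flat zero then positive: no sign change
    with pytest.raises(ValueError):
        zero_crossing(dip, lo=2.0, hi=1.0)


def test_noael_cases():
    horm = DoseResponseSpec("hormesis", {"c": -1.0, "beta": 2.0, "theta": 0.0})
    assert noael(horm) == pytest.approx(0.5, abs=1e-5)  # root of -D + 2 D^2
    flat = DoseResponseSpec("hockey_stick", {"c": 0.0, "dth": 0.5, "beta": 1.0})
    assert noael(flat) is None  # never negative
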