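import numpy as np
import pytest

from cvdmmi.dose_response import DoseResponseSpec
from cvdmmi.fitting import FittedModel
from cvdmmi.hazard_model import BaselineParams, DemParams, HazardModel
from cvdmmi.mmi import (allocate_draws, ic_weights, information_criterion,
                        member_curve, mmi_central, simulate_uncertainty,
                        wald_simulate)


def _lnt_member(beta=0.1, var=0.0025, intercept=np.log(0.01), transfer="ERR"):
    model = HazardModel(
        transfer,
        BaselineParams(values={"intercept": intercept}, active=("intercept",)),
        DoseResponseSpec("lnt", {"beta": beta}),
    )
    return FittedModel(model=model, param_names=["dr:beta"],
                       mle=np.array([beta]), cov=np.array([[var]]),
                       deviance=100.0, npar=1, converged=True)


def test_information_criterion_values():
    assert information_criterion(100.0, 5) == 110.0
    assert information_criterion(13415.77, 16) == pytest.approx(13447.77)
    assert information_criterion(13415.77, 16, "BIC", n=9622) == pytest.approx(13562.52, abs=0.01)
    with pytest.raises(ValueError):
        information_criterion(100.0, 5, "BIC")


def test_ic_weights_basic_properties():
    g = ic_weights([(100.0, 2), (100.0, 2)])
    np.testing.assert_allclose(g.weights, [0.5, 0.5])
    # invariance under a constant shift of all criterion values
    g1 = ic_weights([(100.0, 3), (104.0, 2), (90.0, 8)])
    g2 = ic_weights([(600.0, 3), (604.0, 2), (590.0, 8)])
    np.testing.assert_allclose(g1.weights, g2.weights, atol=1e-12)
    assert g1.delta_ic.min() == 0.0
    assert g1.weights.sum() == pytest.approx(1.0)


def test_allocate_draws_sums_exactly():
    for w in ([0.2412, 0.5823, 0.1765], [1 / 3, 1 / 3, 1 / 3], [0.9999, 0.0001]):
        c = allocate_draws(np.array(w) / np.sum(w), 10_000)
        assert c.sum() == 10_000
        assert np.argmax(c) == np.argmax(w)


def test_mmi_central_is_weighted_pointwise_sum():
    m1 = _lnt_member(beta=0.2)
    m2 = _lnt_member(beta=-0.1)
    g = ic_weights([(100.0, 1), (100.0 - 2 * np.log(3), 1)], names=["a", "b"])
    g.members = [m1, m2]
    w = g.weights
    doses = np.linspace(0, 4, 9)
    np.testing.assert_allclose(
        mmi_central(g, doses),
        w[0] * member_curve(m1, doses) + w[1] * member_curve(m2, doses))
    single = ic_weights([m1])
    np.testing.assert_allclose(mmi_central(single, doses), member_curve(m1, doses))


def test_err_ear_scale_conversion_uses_member_baseline():
    m = _lnt_member(beta=0.2, intercept=np.log(0.01))
    doses = np.array([1.0, 2.0])
    np.testing.assert_allclose(member_curve(m, doses, scale="EAR"),
                               0.01 * member_curve(m, doses, scale="ERR"))
    ear = _lnt_member(beta=0.002, transfer="EAR")
    np.testing.assert_allclose(member_curve(ear, doses, scale="ERR"),
                               member_curve(ear, doses, scale="EAR") / 0.01)


def test_zero_covariance_bands_collapse_to_central():
    m = _lnt_member(beta=0.15, var=0.0)
    g = ic_weights([m])
    s = simulate_uncertainty(g, np.linspace(0.1, 3, 5), total_draws=500, seed=1)
    np.testing.assert_allclose(s.lo95, s.central, atol=1e-12)
    np.testing.assert_allclose(s.hi95, s.central, atol=1e-12)


def test_band_halfwidth_scales_with_covariance():
    doses = np.array([1.0, 2.0])
    g1 = ic_weights([_lnt_member(var=0.0025)])
    g4 = ic_weights([_lnt_member(var=4 * 0.0025)])
    s1 = simulate_uncertainty(g1, doses, total_draws=10_000, seed=3)
    s4 = simulate_uncertainty(g4, doses, total_draws=10_000, seed=3)
    hw1 = (s1.hi95 - s1.lo95) / 2
    hw4 = (s4.hi95 - s4.lo95) / 2
    np.testing.assert_allclose(hw4 / hw1, 2.0, rtol=0.05)


def test_pool_size_and_per_member_seeding():
    m1, m2 = _lnt_member(0.2), _lnt_member(-0.05)
    g = ic_weights([(100.0, 1), (101.0, 1)], names=["a", "b"])
    g.members = [m1, m2]
    s = simulate_uncertainty(g, np.array([1.0]), total_draws=10_000, seed=9, keep_pool=True)
    assert s.n_draws == 10_000
    assert s.pool.shape == (10_000, 1)
    assert s.draw_counts["a"] + s.draw_counts["b"] == 10_000
    # deterministic rerun
    s2 = simulate_uncertainty(g, np.array([1.0]), total_draws=10_000, seed=9, keep_pool=True)
    np.testing.assert_array_equal(s.pool, s2.pool)


def test_non_psd_covariance_is_rejected_by_name():
    bad = _lnt_member()
    bad.cov = np.array([[-1.0]])
    with pytest.raises(ValueError, match="positive semi-definite"):
        wald_simulate(bad, np.array([1.0]), n_draws=10, seed=0, name="bad-member")


def test_err_below_minus_one_draws_are_counted():
    m = _lnt_member(beta=-0.5, var=0.04)  # ERR(4 Gy) = -2 at the MLE
    g = ic_weights([m])
    s = simulate_uncertainty(g, np.array([4.0]), total_draws=2000, seed=5)
    assert s.n_err_below_neg1 > 1000
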