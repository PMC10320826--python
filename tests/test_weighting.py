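import numpy as np
import pytest

from metagaze.observer import info_trace
from metagaze.task import generate_task_design
from metagaze.weighting import (
    WeightingParams,
    kernel,
    make_variant,
    weight_info,
)


@pytest.fixture(scope="module")
def raw_trace():
    return info_trace(generate_task_design(1))


def test_identity_kernel_leaves_gain_unchanged(raw_trace):
    params = WeightingParams(lam0=1.0, lam1=0.0, beta0=0.0, beta1=0.0)
    weighted = weight_info(raw_trace, params)
    np.testing.assert_allclose(
        weighted.frame["ig_weighted"], raw_trace.frame["d_kl"], atol=0
    )


def test_downweight_ratio_closed_form():
    """IG(s=5,t=10)/IG(s=1,t=10) with lam1=0, beta1=0.065 equals
    exp(-4*10*0.065), evaluated independently."""
    params = WeightingParams(lam0=1.0, lam1=0.0, beta0=0.0, beta1=0.065)
    ratio = kernel(5, 10, params) / kernel(1, 10, params)
    assert ratio == pytest.approx(0.07427357821433388, abs=1e-12)


def test_upweight_only_increases_with_sequence(raw_trace):
    params = WeightingParams(lam0=1.0, lam1=0.5, beta0=0.0, beta1=0.0)
    w = weight_info(raw_trace, params).pivot().to_numpy()
    d = raw_trace.pivot().to_numpy()
    factor = w / d
    assert (np.diff(factor, axis=0) > 0).all()


def test_downweight_decreases_with_sequence_at_fixed_trial():
    params = WeightingParams(lam0=1.0, lam1=0.0, beta0=0.1, beta1=0.05)
    for t in (1, 5, 15):
        vals = kernel(np.arange(1, 17), t, params)
        assert (np.diff(vals) < 0).all()


def test_null_kernel_is_constant_across_sequences():
    params = WeightingParams(lam0=0.7, lam1=0.0, beta0=0.2, beta1=0.0)
    for t in (1, 8, 15):
        vals = kernel(np.arange(1, 17), t, params)
        np.testing.assert_allclose(vals, vals[0], rtol=1e-14)


def test_weighting_linear_in_gain(raw_trace):
    params = WeightingParams(lam0=0.8, lam1=0.01, beta0=0.1, beta1=0.02)
    w1 = weight_info(raw_trace, params).frame["ig_weighted"]
    doubled = raw_trace.__class__(
        frame=raw_trace.frame.assign(d_kl=2 * raw_trace.frame["d_kl"]),
        design_seed=raw_trace.design_seed,
    )
    w2 = weight_info(doubled, params).frame["ig_weighted"]
    np.testing.assert_allclose(w2, 2 * w1, rtol=1e-14)


def test_invalid_params_error_names_offending_sequence(raw_trace):
    params = WeightingParams(lam0=1.0, lam1=-0.1, beta0=0.1, beta1=0.0)
    with pytest.raises(ValueError, match="sequence 10"):
        weight_info(raw_trace, params)
    with pytest.raises(ValueError, match="sequence"):
        weight_info(raw_trace, WeightingParams(beta0=0.1, beta1=-0.05))


def test_timescale_form_flips_slope_meaning():
    rate = WeightingParams(lam0=1, beta0=0.1, beta1=0.05, rate_form=True)
    timescale = WeightingParams(lam0=1, beta0=0.5, beta1=0.5, rate_form=False)
    # rate form: larger s decays faster; timescale form: larger s decays slower
    assert kernel(16, 10, rate) < kernel(1, 10, rate)
    assert kernel(16, 10, timescale) > kernel(1, 10, timescale)


@pytest.mark.parametrize(
    "name, free",
    [
        ("null", ()),
        ("upweight", ("lam1",)),
        ("downweight", ("beta1",)),
        ("full", ("lam1", "beta1")),
    ],
)
def test_variant_free_parameters(name, free):
    variant = make_variant(name)
    assert variant.free_params == free
    clamped = variant.clamp(WeightingParams(lam0=2, lam1=0.5, beta0=0.3, beta1=0.4))
    assert (clamped.lam1 == 0.5) == ("lam1" in free)
    assert (clamped.beta1 == 0.4) == ("beta1" in free)
    assert clamped.lam0 == 2 and clamped.beta0 == 0.3


def test_unknown_variant_rejected():
    with pytest.raises(ValueError, match="unknown variant"):
        make_variant("bayesian")


def test_weighted_trace_zero_iff_gain_zero(raw_trace):
    frame = raw_trace.frame.copy()
    frame.loc[frame.index[:3], "d_kl"] = 0.0
    zeroed = raw_trace.__class__(frame=frame, design_seed=raw_trace.design_seed)
    w = weight_info(zeroed, WeightingParams(lam0=1.2, beta0=0.1, beta1=0.01))
    out = w.frame["ig_weighted"].to_numpy()
    assert (out[:3] == 0).all()
    assert (out[3:] > 0).all()
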