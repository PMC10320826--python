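import numpy as np
import pytest

import metagaze as mg
from metagaze.inference import _kernels, build_model, summarize
from metagaze.inference.fit import FitConfig, fit
from metagaze.inference.model import ModelError


@pytest.fixture(scope="module")
def small_model(design, trace, small_cohort):
    return build_model("full", small_cohort, trace)


def test_analytic_gradient_matches_finite_differences(small_model):
    rng = np.random.default_rng(0)
    theta = small_model.initial_point(rng)
    _, grad = small_model.logp_grad(theta)
    eps = 1e-6
    for i in range(small_model.n_params):
        tp = theta.copy()
        tp[i] += eps
        tm = theta.copy()
        tm[i] -= eps
        fd = (small_model.logp(tp) - small_model.logp(tm)) / (2 * eps)
        assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


def test_compiled_and_numpy_likelihood_agree(small_model):
    rng = np.random.default_rng(3)
    theta = small_model.initial_point(rng)
    lp_fast, g_fast = small_model.logp_grad(theta)
    had = _kernels.HAVE_NUMBA
    try:
        _kernels.HAVE_NUMBA = False
        lp_ref, g_ref = small_model.logp_grad(theta)
    finally:
        _kernels.HAVE_NUMBA = had
    assert lp_fast == pytest.approx(lp_ref, rel=1e-12)
    np.testing.assert_allclose(g_fast, g_ref, rtol=1e-9, atol=1e-9)


@pytest.mark.parametrize(
    "variant, n_weighting",
    [("null", 2), ("upweight", 3), ("downweight", 3), ("full", 4)],
)
def test_variant_weighting_parameter_counts(variant, n_weighting, small_cohort, trace):
    model = build_model(variant, small_cohort, trace)
    weighting = [
        n for n in model.scalar_names
        if n in ("log_lam0", "lam1", "log_beta0", "beta1")
    ]
    assert len(weighting) == n_weighting


def test_likelihood_terms_match_nonmissing_cells(small_cohort, trace):
    model = build_model("full", small_cohort, trace)
    frame = small_cohort.frame
    assert model.n_obs["la"] == len(frame)
    n_measured = int(
        (
            (frame["look_away"] == 0)
            & frame["saccadic_latency_ms"].notna()
            & frame["looking_time_ms"].notna()
        ).sum()
    )
    assert model.n_obs["sl"] == n_measured
    assert model.n_obs["lt"] == n_measured


def test_mismatched_design_rejected(trace, small_cohort):
    other = mg.generate_task_design(99)
    table = mg.simulate_cohort(other, mg.CohortConfig(n_infants=5), seed=0)
    with pytest.raises(ModelError, match="different designs"):
        build_model("full", table, trace)


def test_out_of_support_parameters_have_zero_density(small_model):
    theta = small_model.initial_point(np.random.default_rng(1))
    theta[small_model.index["beta1"]] = -5.0  # beta0 + beta1*16 < 0
    lp, grad = small_model.logp_grad(theta)
    assert lp == -np.inf
    assert (grad == 0).all()


def test_fit_determinism(design, trace, small_cohort):
    model = build_model("null", small_cohort, trace)
    cfg = FitConfig(tune=100, draws=100, seed=7)
    a = fit(model, cfg)
    b = fit(model, cfg)
    np.testing.assert_array_equal(
        a.idata.posterior["lam0"].to_numpy(), b.idata.posterior["lam0"].to_numpy()
    )
    assert a.max_rhat == b.max_rhat


class _MockResult:
    """Minimal stand-in exposing a posterior for summarize()."""

    def __init__(self, draws_by_name):
        import xarray as xr
        import arviz as az

        self.idata = az.InferenceData(
            posterior=xr.Dataset(
                {k: (("chain", "draw"), v) for k, v in draws_by_name.items()}
            )
        )


def test_summarize_zero_flag_on_mock_draws():
    rng = np.random.default_rng(0)
    sym = rng.standard_normal((2, 500))
    pos = np.abs(rng.standard_normal((2, 500))) + 0.1
    out = summarize(_MockResult({"sym": sym, "pos": pos}), ["sym", "pos"])
    assert not out.loc["sym", "different_from_zero"]
    assert out.loc["pos", "different_from_zero"]
    with pytest.raises(KeyError):
        summarize(_MockResult({"sym": sym}), ["missing"])


def test_hdi_mass_by_rank_count():
    """~94% of sorted mock draws fall inside the reported interval."""
    rng = np.random.default_rng(8)
    draws = rng.standard_normal((2, 2000))
    out = summarize(_MockResult({"x": draws}), ["x"])
    flat = np.sort(draws.reshape(-1))
    lo, hi = out.loc["x", "hdi_low"], out.loc["x", "hdi_high"]
    inside = int(((flat >= lo) & (flat <= hi)).sum())
    target = int(round(0.94 * flat.size))
    assert abs(inside - target) <= 1
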