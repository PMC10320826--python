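import json
import types

import arviz as az
import numpy as np
import pytest
import xarray as xr

import metagaze as mg
from metagaze.report import make_report, simulate_unseen_sequence


def mock_fit(lam0=1.0, lam1=None, beta0=0.1, beta1=None, sd=0.0, n=400, seed=0):
    """A stand-in posterior (point mass or Gaussian) around given values."""
    rng = np.random.default_rng(seed)

    def draws(center):
        return center + sd * rng.standard_normal((2, n // 2))

    data = {"lam0": draws(lam0), "beta0": draws(beta0)}
    if lam1 is not None:
        data["lam1"] = draws(lam1)
    if beta1 is not None:
        data["beta1"] = draws(beta1)
    idata = az.InferenceData(
        posterior=xr.Dataset({k: (("chain", "draw"), v) for k, v in data.items()})
    )
    return types.SimpleNamespace(idata=idata)


def test_null_posterior_gives_identical_curves(design):
    sim = simulate_unseen_sequence(mock_fit(), design, positions=(1, 5))
    a = sim.curves[sim.curves["position"] == 1]["ig_mean"].to_numpy()
    b = sim.curves[sim.curves["position"] == 5]["ig_mean"].to_numpy()
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_point_mass_posterior_gives_zero_width_bands(design):
    sim = simulate_unseen_sequence(mock_fit(beta1=0.05), design)
    width = sim.curves["ig_high"] - sim.curves["ig_low"]
    np.testing.assert_allclose(width, 0.0, atol=1e-14)


def test_downweight_posterior_orders_position_curves(design):
    """With beta1 > 0 and lam1 = 0: the late-position curve starts level
    with the early one and falls below it on later trials."""
    sim = simulate_unseen_sequence(
        mock_fit(lam1=0.0, beta1=0.065, sd=0.01, n=600), design, positions=(1, 5)
    )
    early = sim.curves[sim.curves["position"] == 1].set_index("trial")["ig_mean"]
    late = sim.curves[sim.curves["position"] == 5].set_index("trial")["ig_mean"]
    assert late.loc[1] <= early.loc[1] * 1.001
    assert (late.loc[5:] < early.loc[5:]).all()
    assert sim.n_draws >= 500


def test_position_out_of_range_rejected(design):
    with pytest.raises(ValueError, match="position"):
        simulate_unseen_sequence(mock_fit(), design, positions=(0,))
    with pytest.raises(ValueError, match="position"):
        simulate_unseen_sequence(mock_fit(), design, positions=(17,))


def test_report_partial_when_inputs_missing(tmp_path, design):
    sim = simulate_unseen_sequence(mock_fit(beta1=0.05), design)
    bundle = make_report(tmp_path / "report", simulation=sim)
    assert not bundle.complete
    manifest = json.loads((tmp_path / "report" / "manifest.json").read_text())
    assert manifest["status"] == "partial"
    assert "unseen_sequence" in manifest["artifacts"]
    assert "model_comparison" in manifest["missing"]
    assert (tmp_path / "report" / "unseen_sequence.png").exists()


def test_report_manifest_is_deterministic(tmp_path, design):
    sim = simulate_unseen_sequence(mock_fit(beta1=0.05), design)
    b1 = make_report(tmp_path / "r1", simulation=sim)
    b2 = make_report(tmp_path / "r2", simulation=sim)
    m1 = (tmp_path / "r1" / "manifest.json").read_bytes()
    m2 = (tmp_path / "r2" / "manifest.json").read_bytes()
    assert m1 == m2


def test_full_report_bundle(tmp_path, variant_fits, comparison, design, efficiency_result):
    sim = simulate_unseen_sequence(variant_fits["full"], design)
    bundle = make_report(
        tmp_path / "full_report",
        fits=variant_fits,
        comparison=comparison,
        simulation=sim,
        efficiency=efficiency_result,
    )
    assert bundle.complete
    manifest = json.loads((bundle.directory / "manifest.json").read_text())
    assert manifest["status"] == "complete"
    for name in bundle.artifacts.values():
        assert (bundle.directory / name).exists()
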