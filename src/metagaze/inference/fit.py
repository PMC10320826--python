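"""Fitting, summarizing and posterior-predictive checking the joint model."""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
import xarray as xr

from .diagnostics import max_split_rhat
from .model import DV_NAMES, ObservationModel
from .sampler import sample_nuts

RHAT_THRESHOLD = 1.05
HDI_PROB = 0.94


class SamplingError(RuntimeError):
    """Raised when sampling fails outright; carries sampler statistics."""

    def __init__(self, message, stats=None):
        super().__init__(message)
        self.stats = stats


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings.

    Defaults are desk-scale; :meth:`study_scale` mirrors a two-chain run
    with a very long warmup and 10,000 retained draws.
    """

    chains: int = 2
    tune: int = 800
    draws: int = 800
    target_accept: float = 0.85
    max_treedepth: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("chains must be >= 2 (required for split-R-hat)")

    @classmethod
    def study_scale(cls, seed: int = 0) -> "FitConfig":
        return cls(chains=2, tune=390_000, draws=10_000, seed=seed)


@dataclass
class FitResult:
    """Posterior draws, diagnostics and provenance for one fitted variant."""

    idata: az.InferenceData
    model: ObservationModel
    config: FitConfig
    max_rhat: float
    converged: bool
    data_hash: str

    @property
    def variant_name(self) -> str:
        return self.model.variant.name

    def posterior(self, name: str) -> np.ndarray:
        return self.idata.posterior[name].to_numpy()


def _natural_draws(model: ObservationModel, draws: np.ndarray) -> dict[str, np.ndarray]:
    """Map free-vector draws (chains, draws, dim) to natural-scale variables."""
    ix = model.index
    out = {}
    out["lam0"] = np.exp(draws[..., ix["log_lam0"]])
    out["beta0"] = np.exp(draws[..., ix["log_beta0"]])
    if model.variant.free_lam1:
        out["lam1"] = draws[..., ix["lam1"]]
    if model.variant.free_beta1:
        out["beta1"] = draws[..., ix["beta1"]]
    for dv in DV_NAMES:
        for letter in "abcd":
            out[f"{letter}_{dv}"] = draws[..., ix[f"{letter}_{dv}"]]
        out[f"tau_{dv}"] = np.exp(draws[..., ix[f"log_tau_{dv}"]])
        out[f"z_{dv}"] = draws[..., model.z_slices[dv]]
    out["sigma_sl"] = np.exp(draws[..., ix["log_sigma_sl"]])
    out["sigma_lt"] = np.exp(draws[..., ix["log_sigma_lt"]])
    return out


def fit(model: ObservationModel, config: FitConfig | None = None) -> FitResult:
    """Sample the posterior of a built model.

    Chains run sequentially with seeds derived from ``config.seed``; two
    fits with identical data, model and config produce identical draws.
    """
    config = config or FitConfig()
    all_draws = []
    all_stats = []
    for chain in range(config.chains):
        rng = np.random.default_rng([config.seed, chain])
        theta0 = model.initial_point(rng)
        draws, stats = sample_nuts(
            model.logp_grad,
            theta0,
            n_tune=config.tune,
            n_draws=config.draws,
            rng=rng,
            target_accept=config.target_accept,
            max_depth=config.max_treedepth,
        )
        if not np.isfinite(stats.lp).all():
            raise SamplingError(
                f"chain {chain} produced non-finite log density", stats
            )
        all_draws.append(draws)
        all_stats.append(stats)
    draws = np.stack(all_draws)  # (chains, draws, dim)

    natural = _natural_draws(model, draws)
    coords = {"infant": model.infant_ids}
    data_vars = {}
    for name, arr in natural.items():
        if arr.ndim == 3:
            data_vars[name] = (("chain", "draw", "infant"), arr)
        else:
            data_vars[name] = (("chain", "draw"), arr)
    posterior = xr.Dataset(data_vars, coords=coords)

    sample_stats = xr.Dataset(
        {
            "lp": (("chain", "draw"), np.stack([s.lp for s in all_stats])),
            "diverging": (("chain", "draw"), np.stack([s.diverging for s in all_stats])),
            "tree_depth": (("chain", "draw"), np.stack([s.tree_depth for s in all_stats])),
            "acceptance_rate": (
                ("chain", "draw"),
                np.stack([s.accept_rate for s in all_stats]),
            ),
        }
    )

    # pointwise log likelihood per measure, for LOO/WAIC
    n_chains, n_draws, _ = draws.shape
    ll = {
        dv: np.empty((n_chains, n_draws, model.n_obs[dv])) for dv in DV_NAMES
    }
    for c in range(n_chains):
        for d in range(n_draws):
            point = model.pointwise_loglik(draws[c, d])
            for dv in DV_NAMES:
                ll[dv][c, d] = point[dv]
    log_likelihood = xr.Dataset(
        {dv: (("chain", "draw", f"{dv}_obs"), ll[dv]) for dv in DV_NAMES}
    )

    idata = az.InferenceData(
        posterior=posterior,
        sample_stats=sample_stats,
        log_likelihood=log_likelihood,
    )
    rhat_inputs = {
        name: arr for name, arr in natural.items()
    }
    worst = max_split_rhat(rhat_inputs)
    return FitResult(
        idata=idata,
        model=model,
        config=config,
        max_rhat=worst,
        converged=bool(worst < RHAT_THRESHOLD),
        data_hash=model.data_hash,
    )


def summarize(result: FitResult, params: list[str] | None = None) -> pd.DataFrame:
    """Posterior mean, SD and 94% HDI per parameter.

    ``different_from_zero`` is True when the HDI excludes zero.  The HDI is
    the narrowest contiguous interval holding 94% of the draws.
    """
    post = result.idata.posterior
    if params is None:
        params = [v for v in post.data_vars if post[v].ndim == 2]
    rows = []
    for name in params:
        if name not in post:
            raise KeyError(f"parameter {name!r} not in posterior")
        vals = post[name].to_numpy()
        if vals.ndim != 2:
            raise KeyError(f"parameter {name!r} is vector-valued; summarize scalars")
        flat = vals.reshape(-1)
        lo, hi = az.hdi(flat, hdi_prob=HDI_PROB)
        rows.append(
            {
                "param": name,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "hdi_low": float(lo),
                "hdi_high": float(hi),
                "different_from_zero": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows).set_index("param")


def posterior_predictive(
    result: FitResult, n_draws: int = 200, seed: int = 0
) -> dict[str, np.ndarray]:
    """Replicate the three measures from the posterior.

    Returns arrays of shape ``(n_draws, n_obs)`` per measure, on the model's
    internal scales (look-away 0/1; SL and log-LT standardized).  With
    ``n_draws=0`` returns empty arrays.
    """
    model = result.model
    post = result.idata.posterior
    n_chains = post.sizes["chain"]
    n_avail = post.sizes["draw"]
    out = {dv: np.empty((n_draws, model.n_obs[dv])) for dv in DV_NAMES}
    if n_draws == 0:
        return out
    rng = np.random.default_rng(seed)
    flat_idx = rng.integers(0, n_chains * n_avail, size=n_draws)
    for j, k in enumerate(flat_idx):
        c, d = divmod(int(k), n_avail)
        p = {}
        for name in post.data_vars:
            arr = post[name].to_numpy()
            p[name] = arr[c, d] if arr.ndim == 2 else arr[c, d, :]
        p.setdefault("lam1", 0.0)
        p.setdefault("beta1", 0.0)
        mus = model.linear_predictors(p)
        out["la"][j] = (rng.random(model.n_obs["la"]) < 1 / (1 + np.exp(-mus["la"]))).astype(float)
        out["sl"][j] = mus["sl"] + p["sigma_sl"] * rng.standard_normal(model.n_obs["sl"])
        out["lt"][j] = mus["lt"] + p["sigma_lt"] * rng.standard_normal(model.n_obs["lt"])
    return out
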