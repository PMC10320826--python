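"""Downstream analyses and report generation.

Two analyses interpret a fitted weighting model:

* the *unseen-sequence simulation*: take a held-out sequence's raw
  information-gain profile and ask how a learner would have perceived it
  early versus late in the session, by applying the posterior weighting
  kernel at different sequence positions;
* figure/report generation: posterior densities for the meta-learning
  slopes, posterior-predictive overlays, the model-comparison table, the
  unseen-sequence panel and the latency-efficiency panel, with a manifest
  recording seeds, configuration hashes and package versions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cohort import scaled_dkl_frame
from .efficiency import EfficiencyResult
from .inference.compare import ComparisonTable, write_comparison
from .inference.fit import FitResult, posterior_predictive
from .observer import info_trace
from .task import TaskDesign


@dataclass(frozen=True)
class SequenceSimulation:
    """Perceived-information curves for one held-out sequence.

    ``curves`` has one row per (position, trial) with the posterior-mean
    weighted IG and a 95% credible band propagated from posterior draws of
    the kernel parameters.
    """

    target_sequence: int
    positions: tuple[int, ...]
    curves: pd.DataFrame
    n_draws: int


def simulate_unseen_sequence(
    result: FitResult,
    design: TaskDesign,
    positions: tuple[int, ...] = (1, 5),
    target_sequence: int | None = None,
    n_draws: int = 500,
    band: float = 0.95,
) -> SequenceSimulation:
    """Apply the posterior weighting kernel to a held-out sequence.

    For each requested session position ``p`` the held-out sequence's D_KL
    profile is weighted as if it had been shown as sequence ``p``:
    ``IG_t = (lam0 + lam1*p) * exp(-t*(beta0 + beta1*p)) * D_KL_t``.
    Under a posterior with mass on ``beta1 > 0`` and ``lam1 ~ 0``, the
    late-position curve starts at the same height but falls below the
    early-position curve on later trials: late evidence is perceived as
    carrying less information once the session's structure is learned.
    """
    n_seq = design.n_sequences
    target_sequence = target_sequence or n_seq
    for p in positions:
        if not 1 <= p <= n_seq:
            raise ValueError(f"position {p} outside 1..{n_seq}")
    if not 1 <= target_sequence <= n_seq:
        raise ValueError(f"target sequence {target_sequence} outside 1..{n_seq}")

    scaled = scaled_dkl_frame(info_trace(design))
    seq = scaled[scaled["sequence"] == target_sequence].sort_values("trial")
    trials = seq["trial"].to_numpy(float)
    d = seq["d_scaled"].to_numpy()

    post = result.idata.posterior
    total = post.sizes["chain"] * post.sizes["draw"]
    n_draws = min(n_draws, total)
    idx = np.linspace(0, total - 1, n_draws).astype(int)

    def flat(name, default=0.0):
        if name in post:
            return post[name].to_numpy().reshape(-1)[idx]
        return np.full(n_draws, default)

    lam0 = flat("lam0")
    lam1 = flat("lam1")
    beta0 = flat("beta0")
    beta1 = flat("beta1")

    lo_q = (1 - band) / 2
    rows = []
    for p in positions:
        lam = lam0 + lam1 * p           # (draws,)
        rate = beta0 + beta1 * p
        curves = lam[:, None] * np.exp(-np.outer(rate, trials)) * d[None, :]
        mean = curves.mean(axis=0)
        lo = np.quantile(curves, lo_q, axis=0)
        hi = np.quantile(curves, 1 - lo_q, axis=0)
        for j, t in enumerate(trials):
            rows.append(
                {
                    "position": int(p),
                    "trial": int(t),
                    "ig_mean": float(mean[j]),
                    "ig_low": float(lo[j]),
                    "ig_high": float(hi[j]),
                }
            )
    return SequenceSimulation(
        target_sequence=int(target_sequence),
        positions=tuple(int(p) for p in positions),
        curves=pd.DataFrame(rows),
        n_draws=n_draws,
    )


@dataclass
class ReportBundle:
    """What :func:`make_report` wrote, and whether anything was missing."""

    directory: Path
    artifacts: dict[str, str]
    missing: list[str]

    @property
    def complete(self) -> bool:
        return not self.missing


def _posterior_density_figure(fits, path):
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    for name, res in fits.items():
        post = res.idata.posterior
        for ax, par in zip(axes, ("lam1", "beta1")):
            if par in post:
                vals = post[par].to_numpy().reshape(-1)
                ax.hist(vals, bins=40, density=True, alpha=0.5, label=name)
    for ax, par in zip(axes, ("lam1", "beta1")):
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel(par)
        ax.legend(fontsize=6)
    axes[0].set_title("early up-weight slope")
    axes[1].set_title("late down-weight slope")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _ppc_figure(result: FitResult, path, n_draws=50, seed=0):
    reps = posterior_predictive(result, n_draws=n_draws, seed=seed)
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    for ax, dv, label in zip(axes, ("sl", "lt"), ("saccadic latency (z)", "log looking time (z)")):
        obs = result.model.blocks[dv]["y"]
        grid = np.linspace(obs.min() - 1, obs.max() + 1, 100)
        for j in range(n_draws):
            ax.hist(
                reps[dv][j], bins=grid, density=True, histtype="step",
                color="C1", alpha=0.15,
            )
        ax.hist(obs, bins=grid, density=True, histtype="step", color="k", lw=1.5)
        ax.set_xlabel(label)
    fig.suptitle("posterior predictive (orange) vs observed (black)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _unseen_figure(sim: SequenceSimulation, path):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for p in sim.positions:
        sub = sim.curves[sim.curves["position"] == p]
        ax.plot(sub["trial"], sub["ig_mean"], label=f"as sequence {p}")
        ax.fill_between(sub["trial"], sub["ig_low"], sub["ig_high"], alpha=0.3)
    ax.set_xlabel("trial")
    ax.set_ylabel("weighted information gain")
    ax.set_title(f"held-out sequence {sim.target_sequence}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _efficiency_figure(res: EfficiencyResult, path):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    me = res.marginal_effects
    ax.plot(me["trial"], me["effect_mean"], color="C0")
    ax.fill_between(me["trial"], me["hdi_low"], me["hdi_high"], alpha=0.3)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("trial")
    ax.set_ylabel("marginal effect of sequence number")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def make_report(
    output_dir,
    fits: dict[str, FitResult] | None = None,
    comparison: ComparisonTable | None = None,
    simulation: SequenceSimulation | None = None,
    efficiency: EfficiencyResult | None = None,
) -> ReportBundle:
    """Write figures, tables and a run manifest into ``output_dir``.

    Missing inputs are tolerated: their panels are listed under ``missing``
    in the manifest and the bundle reports itself as partial.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    missing: list[str] = []

    if fits:
        path = outdir / "posterior_densities.png"
        _posterior_density_figure(fits, path)
        artifacts["posterior_densities"] = path.name
        best = max(fits, key=lambda k: ("beta1" in fits[k].idata.posterior))
        ppc_path = outdir / "posterior_predictive.png"
        _ppc_figure(fits[best], ppc_path)
        artifacts["posterior_predictive"] = ppc_path.name
    else:
        missing += ["posterior_densities", "posterior_predictive"]

    if comparison is not None:
        path = outdir / "model_comparison.csv"
        write_comparison(comparison, path)
        artifacts["model_comparison"] = path.name
    else:
        missing.append("model_comparison")

    if simulation is not None:
        path = outdir / "unseen_sequence.png"
        _unseen_figure(simulation, path)
        artifacts["unseen_sequence"] = path.name
    else:
        missing.append("unseen_sequence")

    if efficiency is not None:
        path = outdir / "efficiency_marginal_effects.png"
        _efficiency_figure(efficiency, path)
        artifacts["efficiency_marginal_effects"] = path.name
    else:
        missing.append("efficiency_marginal_effects")

    import arviz
    import scipy

    manifest = {
        "artifacts": artifacts,
        "missing": missing,
        "status": "complete" if not missing else "partial",
        "fits": {
            name: {
                "variant": res.variant_name,
                "seed": res.config.seed,
                "tune": res.config.tune,
                "draws": res.config.draws,
                "chains": res.config.chains,
                "data_hash": res.data_hash,
                "max_rhat": res.max_rhat,
                "converged": res.converged,
            }
            for name, res in (fits or {}).items()
        },
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "arviz": arviz.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["manifest"] = "manifest.json"
    return ReportBundle(directory=outdir, artifacts=artifacts, missing=missing)
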