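"""Hierarchical observation model linking information gain to gaze measures.

One joint probability model over three dependent measures that share a
single meta-learning weighting kernel:

* look-away ``LA ~ Bernoulli(logit^-1(eta))``,
* saccadic latency ``SL ~ Normal(mu, sigma_sl)`` on the standardized scale,
* looking time ``LT ~ Normal(mu, sigma_lt)`` on the standardized log scale.

Each linear predictor contains an intercept, the weighted information gain
``IG_{s,t}`` (whose regression coefficient is hierarchical: a group mean
plus a per-infant deviation), the centered trial number, and a centered
sequence-number term capturing baseline attention drift across sequences.
The weighting kernel's parameters are shared across all three measures, so
every measure informs the meta-learning parameters jointly.

The model exposes its joint log density and analytic gradient for
gradient-based MCMC, plus pointwise log likelihoods for predictive model
comparison.  Subject deviations use the non-centered parameterization
(``coef_i = b + tau * z_i`` with ``z_i ~ Normal(0, 1)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from ..cohort import GazeTable, scaled_dkl_frame
from ..observer import InfoTrace
from ..weighting import ModelVariant, make_variant

DV_NAMES = ("la", "sl", "lt")


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative default priors; every hyperparameter replaceable.

    Scales refer to the standardized data/covariate scales used internally.
    """

    lam0_scale: float = 1.0      # HalfNormal
    beta0_scale: float = 1.0     # HalfNormal
    lam1_scale: float = 1.0      # Normal(0, .)
    beta1_scale: float = 1.0     # Normal(0, .)
    intercept_scale: float = 2.0
    ig_coef_scale: float = 5.0
    trial_slope_scale: float = 1.0
    attention_slope_scale: float = 1.0
    sigma_scale: float = 1.0     # HalfNormal
    tau_scale: float = 1.0       # HalfNormal


@dataclass(frozen=True)
class ObservationModelSpec:
    """What to fit: a weighting variant plus priors."""

    variant: ModelVariant = field(default_factory=lambda: make_variant("full"))
    priors: PriorSpec = field(default_factory=PriorSpec)
    rate_form: bool = True


class ModelError(ValueError):
    pass


def _logistic(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log1pexp(x):
    out = np.empty_like(x)
    big = x > 30
    out[big] = x[big]
    out[~big] = np.log1p(np.exp(x[~big]))
    return out


class ObservationModel:
    """Fittable joint model over LA, SL and LT for one gaze table.

    Built by :func:`build_model`.  The free-parameter vector ``theta`` is
    ordered as: weighting block (``log_lam0``, optionally ``lam1``,
    ``log_beta0``, optionally ``beta1``), then per measure (la, sl, lt) the
    intercept, group IG coefficient, trial slope and attention slope, then
    ``log_sigma_sl``, ``log_sigma_lt``, ``log_tau_la/sl/lt`` and the
    non-centered subject deviations ``z_la``, ``z_sl``, ``z_lt``.
    """

    def __init__(self, spec: ObservationModelSpec, table: GazeTable, trace: InfoTrace):
        self.spec = spec
        self.variant = spec.variant
        self.priors = spec.priors
        frame = table.frame
        if len(frame) == 0:
            raise ModelError("empty gaze table")
        scaled = scaled_dkl_frame(trace)
        key = scaled.set_index(["sequence", "trial"])["d_scaled"]
        try:
            d = key.loc[list(zip(frame["sequence"], frame["trial"]))].to_numpy()
        except KeyError as err:
            raise ModelError(
                f"gaze table refers to a (sequence, trial) absent from the "
                f"information trace: {err}"
            ) from None
        self.n_sequences = int(scaled["sequence"].max())
        self.t_center = float(scaled["trial"].mean())
        self.s_center = float(scaled["sequence"].mean())

        infants = np.unique(frame["infant_id"].to_numpy())
        self.infant_ids = infants
        self.n_infants = len(infants)
        inf_idx = np.searchsorted(infants, frame["infant_id"].to_numpy())

        s = frame["sequence"].to_numpy(float)
        t = frame["trial"].to_numpy(float)
        attended = frame["look_away"].to_numpy() == 0
        sl_raw = frame["saccadic_latency_ms"].to_numpy(float)
        lt_raw = frame["looking_time_ms"].to_numpy(float)
        keep = attended & np.isfinite(sl_raw) & np.isfinite(lt_raw)

        self.sl_mean = float(np.mean(sl_raw[keep]))
        self.sl_sd = float(np.std(sl_raw[keep]))
        log_lt = np.log(lt_raw[keep])
        self.lt_log_mean = float(np.mean(log_lt))
        self.lt_log_sd = float(np.std(log_lt))

        def block(mask, y):
            return {
                "s": s[mask],
                "t": t[mask],
                "d": d[mask],
                "inf": inf_idx[mask],
                "t_c": t[mask] - self.t_center,
                "s_c": s[mask] - self.s_center,
                "y": y,
            }

        all_mask = np.ones(len(frame), bool)
        self.blocks = {
            "la": block(all_mask, frame["look_away"].to_numpy(float)),
            "sl": block(keep, (sl_raw[keep] - self.sl_mean) / self.sl_sd),
            "lt": block(keep, (log_lt - self.lt_log_mean) / self.lt_log_sd),
        }
        self.n_obs = {k: len(v["y"]) for k, v in self.blocks.items()}

        # free-parameter layout
        names = ["log_lam0"]
        if self.variant.free_lam1:
            names.append("lam1")
        names.append("log_beta0")
        if self.variant.free_beta1:
            names.append("beta1")
        for dv in DV_NAMES:
            names += [f"a_{dv}", f"b_{dv}", f"c_{dv}", f"d_{dv}"]
        names += ["log_sigma_sl", "log_sigma_lt"]
        names += [f"log_tau_{dv}" for dv in DV_NAMES]
        self.scalar_names = list(names)
        self.index = {n: i for i, n in enumerate(names)}
        self.n_scalar = len(names)
        self.z_slices = {}
        start = self.n_scalar
        for dv in DV_NAMES:
            self.z_slices[dv] = slice(start, start + self.n_infants)
            start += self.n_infants
        self.n_params = start

        for blk in self.blocks.values():
            for k in ("s", "t", "d", "t_c", "s_c", "y"):
                blk[k] = np.ascontiguousarray(blk[k], dtype=np.float64)
            blk["inf"] = np.ascontiguousarray(blk["inf"], dtype=np.int64)
            # unique (sequence, trial) combos: kernel and D_KL are shared
            pairs = np.stack([blk["s"], blk["t"]], axis=1)
            uniq, comb = np.unique(pairs, axis=0, return_inverse=True)
            blk["comb"] = np.ascontiguousarray(comb.ravel(), dtype=np.int64)
            blk["u_s"] = np.ascontiguousarray(uniq[:, 0])
            blk["u_t"] = np.ascontiguousarray(uniq[:, 1])
            u_d = np.empty(len(uniq))
            first = np.zeros(len(uniq), dtype=np.int64)
            seen = np.full(len(uniq), -1, dtype=np.int64)
            for row, k in enumerate(blk["comb"]):
                if seen[k] < 0:
                    seen[k] = row
            u_d[:] = blk["d"][seen]
            blk["u_d"] = np.ascontiguousarray(u_d)

        # vectorized prior bookkeeping: every scalar prior is a (half-)normal
        # on the natural scale; log-transformed parameters carry a +theta
        # jacobian term
        pr = self.priors
        scale = np.ones(self.n_params)
        is_log = np.zeros(self.n_params, dtype=bool)
        scale_of = {
            "log_lam0": pr.lam0_scale,
            "lam1": pr.lam1_scale,
            "log_beta0": pr.beta0_scale,
            "beta1": pr.beta1_scale,
            "log_sigma_sl": pr.sigma_scale,
            "log_sigma_lt": pr.sigma_scale,
        }
        for dv in DV_NAMES:
            scale_of[f"a_{dv}"] = pr.intercept_scale
            scale_of[f"b_{dv}"] = pr.ig_coef_scale
            scale_of[f"c_{dv}"] = pr.trial_slope_scale
            scale_of[f"d_{dv}"] = pr.attention_slope_scale
            scale_of[f"log_tau_{dv}"] = pr.tau_scale
        for name, i in self.index.items():
            scale[i] = scale_of[name]
            is_log[i] = name.startswith("log_")
        self._prior_scale2 = scale**2
        self._is_log = is_log

        self.data_hash = _hash_table(frame)

    # -- parameter bookkeeping -------------------------------------------------

    def unpack(self, theta: np.ndarray) -> dict:
        """Natural-scale parameter dictionary from a free vector."""
        ix = self.index
        p = {
            "lam0": float(np.exp(theta[ix["log_lam0"]])),
            "lam1": float(theta[ix["lam1"]]) if self.variant.free_lam1 else 0.0,
            "beta0": float(np.exp(theta[ix["log_beta0"]])),
            "beta1": float(theta[ix["beta1"]]) if self.variant.free_beta1 else 0.0,
            "sigma_sl": float(np.exp(theta[ix["log_sigma_sl"]])),
            "sigma_lt": float(np.exp(theta[ix["log_sigma_lt"]])),
        }
        for dv in DV_NAMES:
            for letter in "abcd":
                p[f"{letter}_{dv}"] = float(theta[ix[f"{letter}_{dv}"]])
            p[f"tau_{dv}"] = float(np.exp(theta[ix[f"log_tau_{dv}"]]))
            p[f"z_{dv}"] = theta[self.z_slices[dv]].copy()
        return p

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        theta = np.zeros(self.n_params)
        theta[self.index["log_beta0"]] = np.log(0.1)
        la_rate = float(np.clip(self.blocks["la"]["y"].mean(), 0.02, 0.98))
        theta[self.index["a_la"]] = np.log(la_rate / (1 - la_rate))
        for dv in DV_NAMES:
            theta[self.index[f"log_tau_{dv}"]] = np.log(0.3)
        jitter = 0.05 * np.ones(self.n_params)
        # keep kernel slopes near zero so beta0 + beta1*s stays in support
        if self.variant.free_lam1:
            jitter[self.index["lam1"]] = 0.002
        if self.variant.free_beta1:
            jitter[self.index["beta1"]] = 0.002
        theta += jitter * rng.standard_normal(self.n_params)
        return theta

    # -- density ----------------------------------------------------------------

    def _kernel_terms(self, p, blk):
        lam = p["lam0"] + p["lam1"] * blk["s"]
        beta = p["beta0"] + p["beta1"] * blk["s"]
        w = lam * np.exp(-blk["t"] * beta)
        return lam, beta, w * blk["d"]

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Joint log posterior density (unnormalized) and its gradient."""
        ix = self.index
        # far outside any plausible scale: treat as zero density (keeps the
        # step-size search and leapfrog integrator overflow-free)
        if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 50.0:
            return -np.inf, np.zeros_like(theta)

        lam0 = np.exp(theta[ix["log_lam0"]])
        lam1 = theta[ix["lam1"]] if self.variant.free_lam1 else 0.0
        beta0 = np.exp(theta[ix["log_beta0"]])
        beta1 = theta[ix["beta1"]] if self.variant.free_beta1 else 0.0
        # positivity of the kernel over the design range is enforced softly
        # by the priors; the hard bounds below are wide numerical guards
        # only (a decay rate of -3 would already explode the likelihood),
        # so the posterior never feels a sharp support edge
        s_end = float(self.n_sequences)
        if (
            lam0 + lam1 * 1.0 <= 0
            or lam0 + lam1 * s_end <= 0
            or beta0 + beta1 * 1.0 < -3.0
            or beta0 + beta1 * s_end < -3.0
        ):
            return -np.inf, np.zeros_like(theta)

        # vectorized (half-)normal priors with log-transform jacobians
        nat = np.where(self._is_log, np.exp(theta), theta)
        ratio2 = nat * nat / self._prior_scale2
        logp = -0.5 * ratio2.sum() + theta[self._is_log].sum()
        grad = np.where(self._is_log, -ratio2 + 1.0, -nat / self._prior_scale2)

        # likelihood blocks
        if _kernels.HAVE_NUMBA:
            logp += self._likelihood_compiled(theta, lam0, lam1, beta0, beta1, grad)
        else:
            logp += self._likelihood_numpy(self.unpack(theta), grad)
        return logp, grad

    def _likelihood_compiled(self, theta, lam0, lam1, beta0, beta1, grad) -> float:
        ix = self.index
        logp = 0.0
        for dv in DV_NAMES:
            blk = self.blocks[dv]
            tau = np.exp(theta[ix[f"log_tau_{dv}"]])
            sigma = np.exp(theta[ix[f"log_sigma_{dv}"]]) if dv != "la" else 1.0
            z = theta[self.z_slices[dv]]
            grad_z = np.zeros(self.n_infants)
            (
                lp, g_a, g_b, g_c, g_d, g_sigma, g_tau,
                g_lam0, g_lam1, g_beta0, g_beta1,
            ) = _kernels.block_logp_grad(
                dv == "la",
                blk["comb"], blk["u_s"], blk["u_t"], blk["u_d"],
                blk["inf"], blk["t_c"], blk["s_c"], blk["y"],
                lam0, lam1, beta0, beta1,
                theta[ix[f"a_{dv}"]], theta[ix[f"b_{dv}"]],
                theta[ix[f"c_{dv}"]], theta[ix[f"d_{dv}"]],
                sigma, tau, z, grad_z,
            )
            logp += lp
            grad[ix[f"a_{dv}"]] += g_a
            grad[ix[f"b_{dv}"]] += g_b
            grad[ix[f"c_{dv}"]] += g_c
            grad[ix[f"d_{dv}"]] += g_d
            if dv != "la":
                grad[ix[f"log_sigma_{dv}"]] += sigma * g_sigma
            grad[self.z_slices[dv]] += grad_z
            grad[ix[f"log_tau_{dv}"]] += tau * g_tau
            grad[ix["log_lam0"]] += lam0 * g_lam0
            if self.variant.free_lam1:
                grad[ix["lam1"]] += g_lam1
            grad[ix["log_beta0"]] += beta0 * g_beta0
            if self.variant.free_beta1:
                grad[ix["beta1"]] += g_beta1
        return logp

    def _likelihood_numpy(self, p, grad) -> float:
        ix = self.index
        logp = 0.0
        for dv in DV_NAMES:
            blk = self.blocks[dv]
            lam, beta, igv = self._kernel_terms(p, blk)
            tau = p[f"tau_{dv}"]
            z = p[f"z_{dv}"]
            coef = p[f"b_{dv}"] + tau * z[blk["inf"]]
            mu = (
                p[f"a_{dv}"]
                + coef * igv
                + p[f"c_{dv}"] * blk["t_c"]
                + p[f"d_{dv}"] * blk["s_c"]
            )
            if dv == "la":
                y = blk["y"]
                logp += float(y @ mu - _log1pexp(mu).sum())
                dmu = y - _logistic(mu)
            else:
                sig = p[f"sigma_{dv}"]
                resid = blk["y"] - mu
                n = len(resid)
                logp += -n * np.log(sig) - 0.5 * float(resid @ resid) / sig**2
                dmu = resid / sig**2
                grad[ix[f"log_sigma_{dv}"]] += -n + float(resid @ resid) / sig**2

            grad[ix[f"a_{dv}"]] += dmu.sum()
            grad[ix[f"b_{dv}"]] += float(dmu @ igv)
            grad[ix[f"c_{dv}"]] += float(dmu @ blk["t_c"])
            grad[ix[f"d_{dv}"]] += float(dmu @ blk["s_c"])
            w_ig = dmu * igv
            grad[self.z_slices[dv]] += tau * np.bincount(
                blk["inf"], weights=w_ig, minlength=self.n_infants
            )
            grad[ix[f"log_tau_{dv}"]] += tau * float(w_ig @ z[blk["inf"]])

            dmu_coef = dmu * coef
            # chain rule through IG = (lam0+lam1 s) exp(-t beta(s)) d
            g_common = dmu_coef * igv
            grad[ix["log_lam0"]] += p["lam0"] * float((g_common / lam).sum())
            if self.variant.free_lam1:
                grad[ix["lam1"]] += float((g_common * blk["s"] / lam).sum())
            grad[ix["log_beta0"]] += p["beta0"] * float((-g_common * blk["t"]).sum())
            if self.variant.free_beta1:
                grad[ix["beta1"]] += float((-g_common * blk["t"] * blk["s"]).sum())

        return logp

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]

    # -- predictive quantities ---------------------------------------------------

    def linear_predictors(self, p: dict) -> dict[str, np.ndarray]:
        out = {}
        for dv in DV_NAMES:
            blk = self.blocks[dv]
            _, _, igv = self._kernel_terms(p, blk)
            coef = p[f"b_{dv}"] + p[f"tau_{dv}"] * p[f"z_{dv}"][blk["inf"]]
            out[dv] = (
                p[f"a_{dv}"]
                + coef * igv
                + p[f"c_{dv}"] * blk["t_c"]
                + p[f"d_{dv}"] * blk["s_c"]
            )
        return out

    def pointwise_loglik(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Per-observation log likelihood of each measure at one draw."""
        p = self.unpack(theta)
        mus = self.linear_predictors(p)
        y_la = self.blocks["la"]["y"]
        out = {"la": y_la * mus["la"] - _log1pexp(mus["la"])}
        for dv in ("sl", "lt"):
            sig = p[f"sigma_{dv}"]
            resid = self.blocks[dv]["y"] - mus[dv]
            out[dv] = -0.5 * np.log(2 * np.pi) - np.log(sig) - 0.5 * (resid / sig) ** 2
        return out


def _hash_table(frame: pd.DataFrame) -> str:
    import hashlib

    buf = frame.to_csv(index=False).encode()
    return hashlib.md5(buf).hexdigest()[:12]


def build_model(
    spec: ObservationModelSpec | str,
    table: GazeTable,
    trace: InfoTrace,
) -> ObservationModel:
    """Build the joint observation model for a gaze table.

    ``spec`` may be a variant name (``"null"``, ``"upweight"``,
    ``"downweight"``, ``"full"``) for default priors.
    """
    if isinstance(spec, str):
        spec = ObservationModelSpec(variant=make_variant(spec))
    if table.design is not None and trace.design_seed not in (-1, table.design.seed):
        raise ModelError(
            "gaze table and information trace come from different designs "
            f"(design seed {table.design.seed} vs trace seed {trace.design_seed})"
        )
    return ObservationModel(spec, table, trace)
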