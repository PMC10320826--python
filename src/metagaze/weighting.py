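"""Meta-learning weighting kernel over information gain.

A learner that meta-learns does not change its world model directly: it
changes how much weight incoming evidence receives.  Here that is expressed
as a multiplicative kernel on the ideal observer's trialwise information
gain,

    IG_{s,t} = (lam0 + lam1 * s) * exp(-t * (beta0 + beta1 * s)) * D_KL_{s,t}

with ``s`` the 1-based sequence index and ``t`` the 1-based trial index.
``lam0`` and ``beta0`` are intercepts; ``lam1`` captures progressive
up-weighting of early-trial information across sequences, and ``beta1``
captures progressively stronger exponential down-weighting of late-trial
information across sequences.  A positive ``beta1`` means that, in later
sequences, evidence arriving late in a sequence is treated as increasingly
irrelevant.

Four model variants switch the two slopes on or off: ``null`` (both fixed at
zero), ``upweight`` (only ``lam1`` free), ``downweight`` (only ``beta1``
free) and ``full`` (both free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observer import InfoTrace

VARIANT_NAMES = ("null", "upweight", "downweight", "full")


@dataclass(frozen=True)
class WeightingParams:
    """Parameters of the weighting kernel.

    ``rate_form=True`` places ``beta0 + beta1*s`` in the exponent as a decay
    *rate*, ``exp(-t*(beta0 + beta1*s))``; the alternative timescale reading
    ``exp(-t/(beta0 + beta1*s))`` is available with ``rate_form=False``.
    Under the rate form a positive ``beta1`` yields stronger late-trial
    down-weighting in later sequences.
    """

    lam0: float = 1.0
    lam1: float = 0.0
    beta0: float = 0.1
    beta1: float = 0.0
    rate_form: bool = True

    def validate(self, max_sequence: int) -> None:
        """Raise if the kernel degenerates anywhere in ``s = 1..max_sequence``."""
        s = np.arange(1, max_sequence + 1)
        lam = self.lam0 + self.lam1 * s
        beta = self.beta0 + self.beta1 * s
        if np.any(lam <= 0):
            s_bad = int(s[np.argmax(lam <= 0)])
            raise ValueError(
                f"lam0 + lam1*s = {self.lam0 + self.lam1 * s_bad:.4g} <= 0 "
                f"at sequence {s_bad}"
            )
        if self.rate_form:
            if np.any(beta < 0):
                s_bad = int(s[np.argmax(beta < 0)])
                raise ValueError(
                    f"beta0 + beta1*s = {self.beta0 + self.beta1 * s_bad:.4g} < 0 "
                    f"at sequence {s_bad}"
                )
        elif np.any(beta <= 0):
            s_bad = int(s[np.argmax(beta <= 0)])
            raise ValueError(
                f"timescale beta0 + beta1*s must be > 0; fails at sequence {s_bad}"
            )


def kernel(s, t, params: WeightingParams) -> np.ndarray:
    """Kernel value at (s, t); broadcasts over array inputs."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    lam = params.lam0 + params.lam1 * s
    beta = params.beta0 + params.beta1 * s
    if params.rate_form:
        return lam * np.exp(-t * beta)
    return lam * np.exp(-t / beta)


@dataclass(frozen=True)
class WeightedInfoTrace:
    """Information gain after meta-learning weighting.

    ``frame`` mirrors the raw trace with an extra ``ig_weighted`` column.
    """

    frame: pd.DataFrame
    params: WeightingParams

    def pivot(self) -> pd.DataFrame:
        return self.frame.pivot(index="sequence", columns="trial", values="ig_weighted")


def weight_info(trace: InfoTrace, params: WeightingParams) -> WeightedInfoTrace:
    """Apply the weighting kernel elementwise to an information-gain trace."""
    max_s = int(trace.frame["sequence"].max())
    params.validate(max_s)
    frame = trace.frame.copy()
    frame["ig_weighted"] = kernel(
        frame["sequence"].to_numpy(), frame["trial"].to_numpy(), params
    ) * frame["d_kl"].to_numpy()
    return WeightedInfoTrace(frame=frame, params=params)


@dataclass(frozen=True)
class ModelVariant:
    """One of the four weighting-model variants compared against each other."""

    name: str
    free_lam1: bool
    free_beta1: bool

    @property
    def free_params(self) -> tuple[str, ...]:
        out = []
        if self.free_lam1:
            out.append("lam1")
        if self.free_beta1:
            out.append("beta1")
        return tuple(out)

    def clamp(self, params: WeightingParams) -> WeightingParams:
        """Zero out the slopes this variant fixes."""
        return WeightingParams(
            lam0=params.lam0,
            lam1=params.lam1 if self.free_lam1 else 0.0,
            beta0=params.beta0,
            beta1=params.beta1 if self.free_beta1 else 0.0,
            rate_form=params.rate_form,
        )


def make_variant(name: str) -> ModelVariant:
    """Build a variant by name: null, upweight, downweight or full."""
    if name not in VARIANT_NAMES:
        raise ValueError(f"unknown variant {name!r}; choose from {VARIANT_NAMES}")
    return ModelVariant(
        name=name,
        free_lam1=name in ("upweight", "full"),
        free_beta1=name in ("downweight", "full"),
    )


def write_weighted_trace(trace: WeightedInfoTrace, path) -> None:
    trace.frame.to_csv(path, index=False)
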