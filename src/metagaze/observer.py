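"""Bayes-optimal ideal observer over target locations.

The observer tracks a Dirichlet-categorical belief over the ``K = 4`` target
locations.  Starting from the uniform prior ``gamma = [1, 1, 1, 1]`` the
posterior-predictive probability of location ``i`` after ``t`` observations is

    P(X)_{s,t}[i] = (X_{s,t}[i] + gamma[i]) / (t + K),

where ``X_{s,t}[i]`` counts how often location ``i`` has been the target so
far in the current sequence.  Beliefs are sequence-local: the count vector
resets at every new sequence.

The information gain of a trial is the Kullback-Leibler divergence (in nats)
between the predictive distribution after and before the observation:

    D_KL = sum_i P_t[i] * log(P_t[i] / P_{t-1}[i]).

It is largest when an observation substantially reorganizes the predictive
distribution -- early trials, or surprising locations -- and decays toward
zero as evidence accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .task import N_LOCATIONS, TaskDesign


@dataclass(frozen=True)
class BeliefState:
    """Dirichlet pseudo-counts of the ideal observer within one sequence."""

    prior_counts: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    observed_counts: tuple[int, ...] = (0, 0, 0, 0)
    t: int = 0

    def __post_init__(self):
        if len(self.prior_counts) != len(self.observed_counts):
            raise ValueError("prior and observed count vectors differ in length")
        if sum(self.observed_counts) != self.t:
            raise ValueError("observed counts do not sum to t")

    @property
    def n_locations(self) -> int:
        return len(self.prior_counts)


def fresh_state(n_locations: int = N_LOCATIONS) -> BeliefState:
    """Belief at the start of a sequence: uniform prior, nothing observed."""
    return BeliefState(
        prior_counts=(1.0,) * n_locations,
        observed_counts=(0,) * n_locations,
        t=0,
    )


def update_belief(state: BeliefState, observed: int) -> BeliefState:
    """Return the belief after observing the target at ``observed`` (1-based)."""
    if not 1 <= observed <= state.n_locations:
        raise ValueError(
            f"location {observed} outside 1..{state.n_locations}"
        )
    counts = list(state.observed_counts)
    counts[observed - 1] += 1
    return BeliefState(
        prior_counts=state.prior_counts,
        observed_counts=tuple(counts),
        t=state.t + 1,
    )


def predictive(state: BeliefState) -> np.ndarray:
    """Posterior-predictive location probabilities; sums to one."""
    counts = np.asarray(state.observed_counts, dtype=float)
    gamma = np.asarray(state.prior_counts, dtype=float)
    return (counts + gamma) / (state.t + gamma.sum())


def kl_divergence(p_new: np.ndarray, p_old: np.ndarray) -> float:
    """KL divergence ``D(p_new || p_old)`` in nats.

    Both arguments must be strictly positive probability vectors, which is
    guaranteed for Dirichlet-smoothed predictives.
    """
    p_new = np.asarray(p_new, dtype=float)
    p_old = np.asarray(p_old, dtype=float)
    if np.any(p_new <= 0) or np.any(p_old <= 0):
        raise ValueError("KL divergence requires strictly positive probabilities")
    return float(rel_entr(p_new, p_old).sum())


@dataclass(frozen=True)
class InfoTrace:
    """Per-trial information gain for a task design.

    ``frame`` has columns ``sequence, trial, location, d_kl`` with 1-based
    indices; ``d_kl`` is in nats.
    """

    frame: pd.DataFrame
    design_seed: int = -1

    def pivot(self) -> pd.DataFrame:
        """Sequences as rows, trials as columns (NaN where a trial is absent)."""
        return self.frame.pivot(index="sequence", columns="trial", values="d_kl")

    def lookup(self) -> dict[tuple[int, int], float]:
        return {
            (int(r.sequence), int(r.trial)): float(r.d_kl)
            for r in self.frame.itertuples()
        }


def info_trace(design: TaskDesign) -> InfoTrace:
    """Information-gain series for every trial of a design.

    The belief resets to the uniform prior at each sequence start, so trial 1
    of every sequence carries the same D_KL no matter which location appears
    (symmetry of the uniform prior).
    """
    rows = []
    for seq in design.sequences:
        state = fresh_state(design.n_locations)
        p_old = predictive(state)
        for t, loc in enumerate(seq.trial_locations, start=1):
            state = update_belief(state, loc)
            p_new = predictive(state)
            rows.append(
                {
                    "sequence": seq.sequence_number,
                    "trial": t,
                    "location": loc,
                    "d_kl": kl_divergence(p_new, p_old),
                }
            )
            p_old = p_new
    return InfoTrace(frame=pd.DataFrame(rows), design_seed=design.seed)


def sequence_dkl(locations, n_locations: int = N_LOCATIONS) -> np.ndarray:
    """D_KL series for a single observation list, from a fresh uniform prior."""
    state = fresh_state(n_locations)
    p_old = predictive(state)
    out = []
    for loc in locations:
        state = update_belief(state, int(loc))
        p_new = predictive(state)
        out.append(kl_divergence(p_new, p_old))
        p_old = p_new
    return np.asarray(out)


def write_trace(trace: InfoTrace, path) -> None:
    """Write the information-gain series as delimited text."""
    trace.frame.to_csv(path, index=False)


def read_trace(path) -> InfoTrace:
    frame = pd.read_csv(path)
    required = {"sequence", "trial", "d_kl"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"info trace missing columns: {sorted(missing)}")
    return InfoTrace(frame=frame)
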