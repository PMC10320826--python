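"""Probabilistic cue-target task structure.

The task is a fixed schedule of sequences, each a run of cue-target trials in
which the target appears in one of ``K = 4`` screen quadrants.  Within a
sequence one quadrant is the *high-likelihood location*: the target appears
there on 60%, 80% or 100% of trials depending on the sequence's
predictability level.  Across the whole design every quadrant serves as
target equally often (a 25% marginal), so that nothing about a location per
se is informative -- only the within-sequence statistics are.

The default design has 16 sequences of 15 trials (six 60% sequences, six 80%
sequences, four 100% sequences) and the very first sequence is always fully
predictable, so the learner's first exposure is to a maximally learnable
environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import numpy as np
import pandas as pd

N_LOCATIONS = 4
TRIALS_PER_SEQUENCE = 15
DEFAULT_SCHEDULE: tuple[tuple[float, int], ...] = ((0.60, 6), (0.80, 6), (1.00, 4))


class DesignError(ValueError):
    """Raised when a task-design schedule is infeasible or malformed."""


@dataclass(frozen=True)
class SequenceSpec:
    """One sequence of the task.

    Parameters
    ----------
    sequence_number
        1-based position of the sequence in the session.
    high_prob_location
        The high-likelihood quadrant, in ``1..4``.
    high_prob
        Probability level of the high-likelihood location (0.60, 0.80 or 1.0).
        Levels are exact within-sequence proportions, not Bernoulli rates:
        a 0.60 sequence of 15 trials contains exactly 9 high-location trials.
    trial_locations
        Target location of each trial, in presentation order.
    """

    sequence_number: int
    high_prob_location: int
    high_prob: float
    trial_locations: tuple[int, ...]

    @property
    def n_trials(self) -> int:
        return len(self.trial_locations)

    @property
    def n_high(self) -> int:
        return sum(1 for x in self.trial_locations if x == self.high_prob_location)


@dataclass(frozen=True)
class TaskDesign:
    """An ordered collection of :class:`SequenceSpec` plus its seed."""

    sequences: tuple[SequenceSpec, ...]
    seed: int
    n_locations: int = N_LOCATIONS

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_trials_total(self) -> int:
        return sum(s.n_trials for s in self.sequences)

    def location_counts(self) -> np.ndarray:
        """Per-location target counts across all trials (index 0 = location 1)."""
        counts = np.zeros(self.n_locations, dtype=int)
        for s in self.sequences:
            for x in s.trial_locations:
                counts[x - 1] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sequences:
            for t, loc in enumerate(s.trial_locations, start=1):
                rows.append(
                    {
                        "sequence": s.sequence_number,
                        "trial": t,
                        "location": loc,
                        "high_prob": s.high_prob,
                        "is_high_location": int(loc == s.high_prob_location),
                    }
                )
        return pd.DataFrame(rows)


def _expand_schedule(schedule, n_trials):
    """Per-sequence (level, n_high) pairs, first sequence fully predictable."""
    levels = []
    for prob, count in schedule:
        if not 0.0 < prob <= 1.0:
            raise DesignError(f"predictability level {prob} outside (0, 1]")
        if count <= 0 or count != int(count):
            raise DesignError(f"sequence count {count} must be a positive integer")
        levels.extend([float(prob)] * int(count))
    n_high = {p: round(p * n_trials) for p, _ in schedule}
    return levels, n_high


def _assign_levels(levels, rng):
    """Order predictability levels over sequence positions.

    The first position always receives a fully-predictable sequence when one
    exists; the remaining levels are shuffled deterministically by the seed.
    """
    levels = list(levels)
    first = None
    if 1.0 in levels:
        levels.remove(1.0)
        first = 1.0
    order = list(rng.permutation(len(levels)))
    shuffled = [levels[i] for i in order]
    return ([first] + shuffled) if first is not None else shuffled


def _assign_high_locations(seq_levels, n_high, n_locations, quota, rng):
    """Greedy balanced assignment of high-likelihood locations.

    Sequences are processed in decreasing order of their high-trial count and
    each is assigned to the location with the smallest running high-trial
    total (ties broken by a seeded permutation), which keeps the residual
    off-trial demand feasible for the default schedule family.
    """
    totals = np.zeros(n_locations, dtype=float)
    high_loc = [0] * len(seq_levels)
    order = sorted(range(len(seq_levels)), key=lambda i: -n_high[seq_levels[i]])
    tiebreak = rng.permutation(n_locations)
    for i in order:
        # smallest total wins; seeded tie-break
        keys = [(totals[loc], tiebreak[loc]) for loc in range(n_locations)]
        loc = min(range(n_locations), key=lambda k: keys[k])
        high_loc[i] = loc + 1
        totals[loc] += n_high[seq_levels[i]]
    need = quota - totals
    if np.any(need < 0):
        raise DesignError(
            "infeasible schedule: high-location trials alone exceed the "
            f"equal 25% per-location marginal (needs {need.tolist()})"
        )
    return high_loc, need.astype(int)


def _allocate_off_trials(seq_levels, high_loc, n_high, need, n_trials, n_locations, rng):
    """Backtracking allocation of off-location trial counts.

    Finds per-sequence counts of low-probability-location trials such that
    every location's global target count is exact and every probabilistic
    sequence uses at least two distinct low-probability locations.
    """
    n_seq = len(seq_levels)
    off_counts = [n_trials - n_high[seq_levels[i]] for i in range(n_seq)]
    # process sequences with the fewest off trials last: they are the most
    # constrained consumers, larger ones give the search room early
    order = sorted(range(n_seq), key=lambda i: -off_counts[i])
    need = need.copy()
    result: list[dict[int, int] | None] = [None] * n_seq

    def compositions(m, allowed, caps):
        """Ways to split m off trials over allowed locations, >=2 parts if m>=2."""
        out = []

        def rec(idx, left, current):
            if idx == len(allowed):
                if left == 0:
                    parts = sum(1 for v in current if v > 0)
                    if m < 2 or parts >= 2:
                        out.append(dict((allowed[j], current[j]) for j in range(len(allowed)) if current[j]))
                return
            hi = min(left, caps[idx])
            for v in range(hi, -1, -1):
                rec(idx + 1, left - v, current + [v])

        rec(0, m, [])
        # prefer balanced allocations toward high-need locations
        out.sort(key=lambda d: -sum(min(v, 1) for v in d.values()))
        return out

    def feasible(pos):
        remaining = need.sum()
        slots = sum(off_counts[order[j]] for j in range(pos, n_seq))
        if remaining != slots:
            return False
        for loc in range(n_locations):
            if need[loc] > sum(
                off_counts[order[j]]
                for j in range(pos, n_seq)
                if high_loc[order[j]] != loc + 1
            ):
                return False
        return True

    def solve(pos):
        if pos == n_seq:
            return bool(np.all(need == 0))
        i = order[pos]
        m = off_counts[i]
        if m == 0:
            result[i] = {}
            return solve(pos + 1)
        allowed = [loc + 1 for loc in range(n_locations) if loc + 1 != high_loc[i]]
        perm = rng.permutation(len(allowed))
        allowed = [allowed[j] for j in perm]
        caps = [int(need[loc - 1]) for loc in allowed]
        for combo in compositions(m, allowed, caps):
            for loc, v in combo.items():
                need[loc - 1] -= v
            if feasible(pos + 1):
                result[i] = combo
                if solve(pos + 1):
                    return True
                result[i] = None
            for loc, v in combo.items():
                need[loc - 1] += v
        return False

    if not solve(0):
        raise DesignError(
            "infeasible schedule: no off-trial allocation satisfies the exact "
            "25% per-location marginal with >=2 low-probability locations"
        )
    return result


def generate_task_design(
    seed: int,
    schedule: TypingSequence[tuple[float, int]] | None = None,
    n_trials: int = TRIALS_PER_SEQUENCE,
    n_locations: int = N_LOCATIONS,
) -> TaskDesign:
    """Generate a pseudo-randomized task design.

    Parameters
    ----------
    seed
        Seed controlling level ordering, high-location assignment, the
        identity of low-probability locations and within-sequence trial order.
        Identical seeds give identical designs.
    schedule
        ``(high_prob, n_sequences)`` pairs; defaults to six 60%, six 80% and
        four 100% sequences.

    Raises
    ------
    DesignError
        If the schedule cannot meet the exact equal-marginal constraint.
    """
    schedule = tuple(schedule) if schedule is not None else DEFAULT_SCHEDULE
    rng = np.random.default_rng(seed)
    levels, n_high = _expand_schedule(schedule, n_trials)
    total = len(levels) * n_trials
    if total % n_locations != 0:
        raise DesignError(
            f"infeasible schedule: {total} total trials not divisible by "
            f"{n_locations} locations (exact 25% marginal unsatisfiable)"
        )
    quota = total // n_locations
    seq_levels = _assign_levels(levels, rng)
    high_loc, need = _assign_high_locations(seq_levels, n_high, n_locations, quota, rng)
    off = _allocate_off_trials(seq_levels, high_loc, n_high, need, n_trials, n_locations, rng)

    sequences = []
    for i, level in enumerate(seq_levels):
        locs = [high_loc[i]] * n_high[level]
        for loc, v in sorted(off[i].items()):
            locs.extend([loc] * v)
        locs = [int(x) for x in rng.permutation(locs)]
        sequences.append(
            SequenceSpec(
                sequence_number=i + 1,
                high_prob_location=high_loc[i],
                high_prob=level,
                trial_locations=tuple(locs),
            )
        )
    return TaskDesign(sequences=tuple(sequences), seed=seed, n_locations=n_locations)


def validate_design(design: TaskDesign) -> list[str]:
    """Check every design invariant; return human-readable violations.

    An empty list means the design is valid.  Validation never raises.
    """
    violations: list[str] = []
    n_loc = design.n_locations
    for s in design.sequences:
        if not 1 <= s.high_prob_location <= n_loc:
            violations.append(
                f"sequence {s.sequence_number}: high location "
                f"{s.high_prob_location} outside 1..{n_loc}"
            )
        bad = [x for x in s.trial_locations if not 1 <= x <= n_loc]
        if bad:
            violations.append(
                f"sequence {s.sequence_number}: locations {bad} outside 1..{n_loc}"
            )
        expected_high = round(s.high_prob * s.n_trials)
        if s.n_high != expected_high:
            violations.append(
                f"sequence {s.sequence_number}: {s.n_high} high-location trials, "
                f"expected exactly {expected_high} for level {s.high_prob:.0%}"
            )
        if s.high_prob < 1.0:
            off_locs = {x for x in s.trial_locations if x != s.high_prob_location}
            if s.n_trials - s.n_high >= 2 and len(off_locs) < 2:
                violations.append(
                    f"sequence {s.sequence_number}: probabilistic sequence uses "
                    f"{len(off_locs)} low-probability location(s), needs >= 2"
                )
    counts = design.location_counts()
    if len(set(counts.tolist())) > 1:
        violations.append(
            f"global marginal: per-location target counts {counts.tolist()} are "
            "not equal (each location must be target on exactly 25% of trials)"
        )
    return violations


def write_design(design: TaskDesign, path) -> None:
    """Write a design as a delimited text table (1-based indices)."""
    design.to_frame().to_csv(path, index=False)


def read_design(path, seed: int = -1) -> TaskDesign:
    """Read a design table written by :func:`write_design`.

    The seed of a round-tripped design is not recoverable from the table and
    defaults to ``-1`` unless supplied.
    """
    df = pd.read_csv(path)
    required = {"sequence", "trial", "location", "high_prob", "is_high_location"}
    missing = required - set(df.columns)
    if missing:
        raise DesignError(f"design table missing columns: {sorted(missing)}")
    sequences = []
    for snum, grp in df.groupby("sequence", sort=True):
        grp = grp.sort_values("trial")
        high_rows = grp[grp["is_high_location"] == 1]
        if len(high_rows):
            high_loc = int(high_rows["location"].iloc[0])
        else:  # degenerate table: infer the modal location
            high_loc = int(grp["location"].mode().iloc[0])
        sequences.append(
            SequenceSpec(
                sequence_number=int(snum),
                high_prob_location=high_loc,
                high_prob=float(grp["high_prob"].iloc[0]),
                trial_locations=tuple(int(x) for x in grp["location"]),
            )
        )
    return TaskDesign(sequences=tuple(sequences), seed=seed)
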