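import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metagaze.observer import (
    fresh_state,
    info_trace,
    kl_divergence,
    predictive,
    read_trace,
    sequence_dkl,
    update_belief,
    write_trace,
)
from metagaze.task import generate_task_design


def brute_force_predictive(observations, n_locations=4):
    """Independent oracle: count occurrences from the raw list, add the
    uniform prior pseudo-count, and normalize."""
    counts = np.array(
        [sum(1 for o in observations if o == loc) for loc in range(1, n_locations + 1)],
        dtype=float,
    )
    smoothed = counts + 1.0
    return smoothed / smoothed.sum()


def run_updates(observations):
    state = fresh_state()
    for o in observations:
        state = update_belief(state, o)
    return state


def test_uniform_prior_predictive_is_exactly_quarter():
    assert predictive(fresh_state()).tolist() == [0.25, 0.25, 0.25, 0.25]


@pytest.mark.parametrize(
    "observations, expected",
    [
        ([1], [0.4, 0.2, 0.2, 0.2]),
        ([1, 1, 2], [3 / 7, 2 / 7, 1 / 7, 1 / 7]),
        ([1] * 15, [16 / 19, 1 / 19, 1 / 19, 1 / 19]),
    ],
)
def test_predictive_closed_form(observations, expected):
    np.testing.assert_allclose(
        predictive(run_updates(observations)), expected, atol=1e-15
    )


@given(st.lists(st.integers(1, 4), max_size=40))
@settings(max_examples=200, deadline=None)
def test_predictive_matches_counting_oracle(observations):
    p = predictive(run_updates(observations))
    np.testing.assert_allclose(p, brute_force_predictive(observations), atol=1e-12)
    assert abs(p.sum() - 1.0) < 1e-12
    assert (p > 0).all()


def test_update_belief_increments_only_observed():
    state = update_belief(fresh_state(), 3)
    assert state.t == 1
    assert state.observed_counts == (0, 0, 1, 0)


def test_invalid_location_rejected():
    with pytest.raises(ValueError, match="outside"):
        update_belief(fresh_state(), 5)


def test_kl_identity_is_zero():
    p = np.array([0.4, 0.2, 0.2, 0.2])
    assert kl_divergence(p, p) == 0.0


@pytest.mark.parametrize(
    "p_new, p_old, expected",
    [
        ([0.4, 0.2, 0.2, 0.2], [0.25] * 4, 0.05411532090976842),
        ([0.5, 1 / 6, 1 / 6, 1 / 6], [0.4, 0.2, 0.2, 0.2], 0.02041099726012753),
    ],
)
def test_kl_frozen_values(p_new, p_old, expected):
    assert kl_divergence(np.array(p_new), np.array(p_old)) == pytest.approx(
        expected, abs=1e-12
    )


def test_kl_rejects_zero_entries():
    with pytest.raises(ValueError, match="positive"):
        kl_divergence(np.array([1.0, 0.0, 0.0, 0.0]), np.array([0.25] * 4))


def test_fully_predictable_sequence_has_strictly_decreasing_gain():
    gains = sequence_dkl([2] * 15)
    assert (np.diff(gains) < 0).all()
    assert (gains > 0).all()


def test_first_trial_gain_identical_across_sequences():
    design = generate_task_design(2)
    trace = info_trace(design)
    first = trace.frame[trace.frame["trial"] == 1]["d_kl"]
    np.testing.assert_allclose(first, first.iloc[0], rtol=1e-12)


def test_gain_nonnegative_everywhere():
    for seed in (0, 1, 2):
        trace = info_trace(generate_task_design(seed))
        assert (trace.frame["d_kl"] >= 0).all()


def test_belief_is_sequence_local():
    """Reversing sequence order permutes the per-sequence gain blocks."""
    from metagaze.task import TaskDesign, SequenceSpec

    design = generate_task_design(4)
    reversed_seqs = tuple(
        SequenceSpec(
            sequence_number=i + 1,
            high_prob_location=s.high_prob_location,
            high_prob=s.high_prob,
            trial_locations=s.trial_locations,
        )
        for i, s in enumerate(reversed(design.sequences))
    )
    rev = TaskDesign(sequences=reversed_seqs, seed=design.seed)
    a = info_trace(design).pivot().to_numpy()
    b = info_trace(rev).pivot().to_numpy()
    np.testing.assert_allclose(a, b[::-1], atol=0)


def test_trace_round_trip(tmp_path, design):
    trace = info_trace(design)
    path = tmp_path / "trace.csv"
    write_trace(trace, path)
    back = read_trace(path)
    np.testing.assert_allclose(back.frame["d_kl"], trace.frame["d_kl"])
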