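import numpy as np
import pandas as pd
import pytest

import metagaze as mg
from metagaze.cohort import CohortConfig, CohortError, GAZE_COLUMNS


def test_seeded_determinism(design):
    a = mg.simulate_cohort(design, seed=11)
    b = mg.simulate_cohort(design, seed=11)
    pd.testing.assert_frame_equal(a.frame, b.frame)
    c = mg.simulate_cohort(design, seed=12)
    assert not a.frame.equals(c.frame)


def test_truncation_stops_sequence_at_first_lookaway(design):
    table = mg.simulate_cohort(design, seed=0)
    for (_, _), grp in table.frame.groupby(["infant_id", "sequence"]):
        la = grp.sort_values("trial")["look_away"].to_numpy()
        assert not la[:-1].any()  # look-away only ever on the last record
    la_rows = table.frame[table.frame["look_away"] == 1]
    assert la_rows["saccadic_latency_ms"].isna().all()
    assert la_rows["looking_time_ms"].isna().all()


def test_locations_follow_design(design):
    table = mg.simulate_cohort(design, seed=1)
    lookup = {
        (s.sequence_number, t): loc
        for s in design.sequences
        for t, loc in enumerate(s.trial_locations, start=1)
    }
    recorded = table.frame[["sequence", "trial", "location"]].drop_duplicates()
    for r in recorded.itertuples():
        assert lookup[(r.sequence, r.trial)] == r.location


def test_exclusion_boundary(design):
    table = mg.simulate_cohort(design, CohortConfig(n_infants=40), seed=9)
    counts = table.trials_per_infant()
    excluded = mg.apply_exclusion(table, min_trials=20)
    kept = excluded.frame.groupby("infant_id").size()
    assert (kept >= 20).all()
    assert excluded.n_excluded == int((counts < 20).sum())
    # boundary: a synthetic infant with exactly 20 trials is retained
    frame = table.frame[table.frame["infant_id"] == counts.index[0]].head(0)
    rows = []
    for t in range(1, 16):
        rows.append((999, 1, t, design.sequences[0].trial_locations[t - 1], 0, 300.0, 1500.0))
    for t in range(1, 6):
        rows.append((999, 2, t, design.sequences[1].trial_locations[t - 1], 0, 300.0, 1500.0))
    twenty = pd.DataFrame(rows, columns=list(GAZE_COLUMNS))
    padded = mg.GazeTable(frame=twenty, design=design)
    assert mg.apply_exclusion(padded, 20).n_infants == 1
    nineteen = mg.GazeTable(frame=twenty.iloc[:-1], design=design)
    assert mg.apply_exclusion(nineteen, 20).n_infants == 0


def test_exclusion_identity_when_all_pass(design):
    table = mg.simulate_cohort(design, seed=3)
    big = mg.apply_exclusion(table, min_trials=1)
    pd.testing.assert_frame_equal(big.frame, table.frame)


def test_round_trip(design, tmp_path):
    table = mg.simulate_cohort(design, mg.CohortConfig(n_infants=10), seed=4)
    path = tmp_path / "gaze.csv"
    mg.write_gaze_table(table, path)
    back = mg.read_gaze_table(path, design=design)
    pd.testing.assert_frame_equal(back.frame, table.frame)


def test_read_rejects_record_after_lookaway(tmp_path, design):
    frame = pd.DataFrame(
        [
            (1, 1, 1, design.sequences[0].trial_locations[0], 1, None, None),
            (1, 1, 2, design.sequences[0].trial_locations[1], 0, 300.0, 1000.0),
        ],
        columns=list(GAZE_COLUMNS),
    )
    path = tmp_path / "bad.csv"
    frame.to_csv(path, index=False)
    with pytest.raises(CohortError, match="truncation"):
        mg.read_gaze_table(path)


def test_read_rejects_measured_lookaway_trial(tmp_path):
    frame = pd.DataFrame(
        [(1, 1, 1, 2, 1, 355.0, None)], columns=list(GAZE_COLUMNS)
    )
    path = tmp_path / "bad2.csv"
    frame.to_csv(path, index=False)
    with pytest.raises(CohortError, match="saccadic_latency_ms"):
        mg.read_gaze_table(path)


def test_read_header_only_file(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text(",".join(GAZE_COLUMNS) + "\n")
    table = mg.read_gaze_table(path)
    assert len(table.frame) == 0


def test_zero_effect_config_gives_flat_latency(design):
    """With all IG coefficients off, simulated latency does not depend on
    information gain (regression slope ~ 0 at large n)."""
    config = CohortConfig(
        n_infants=150, coef_la=0.0, coef_sl=0.0, coef_lt=0.0,
        subject_sd_la=1e-6, subject_sd_sl=1e-6, subject_sd_lt=1e-6,
        trial_slope_la=0.0, trial_slope_sl=0.0, trial_slope_lt=0.0,
        attention_slope_la=0.0, attention_slope_sl=0.0, attention_slope_lt=0.0,
    )
    table = mg.simulate_cohort(design, config, seed=21)
    from metagaze.cohort import scaled_dkl_frame
    from metagaze.weighting import kernel

    scaled = scaled_dkl_frame(mg.info_trace(design))
    key = scaled.set_index(["sequence", "trial"])["d_scaled"]
    sub = table.frame[table.frame["look_away"] == 0]
    ig = kernel(
        sub["sequence"].to_numpy(), sub["trial"].to_numpy(), config.weighting
    ) * key.loc[list(zip(sub["sequence"], sub["trial"]))].to_numpy()
    sl = sub["saccadic_latency_ms"].to_numpy()
    slope = np.polyfit(ig, (sl - sl.mean()) / sl.std(), 1)[0]
    assert abs(slope) < 0.05


def test_downweighting_truncates_later_sequences_earlier(design):
    """With the look-away IG effect on and downweighting, later sequences
    lose their informative early trials, so truncation comes sooner."""
    config = CohortConfig(
        n_infants=400, dropout_hazard=0.0,
        attention_slope_la=0.0, trial_slope_la=0.0,
    )
    table = mg.simulate_cohort(design, config, seed=13)
    watched = table.frame.groupby(["infant_id", "sequence"]).size().reset_index(name="n")
    early = watched[watched["sequence"] <= 4]["n"].mean()
    late = watched[watched["sequence"] >= 13]["n"].mean()
    assert late < early


def test_latency_learning_generator_schema(design):
    table = mg.simulate_latency_learning(design, n_infants=5, seed=1)
    assert set(table.frame.columns) == set(GAZE_COLUMNS)
    assert (table.frame["trial"] >= 2).all()
    high = {s.sequence_number: s.high_prob_location for s in design.sequences}
    assert all(
        high[r.sequence] == r.location for r in table.frame.itertuples()
    )
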