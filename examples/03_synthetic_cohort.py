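"""Simulate a synthetic infant cohort and inspect its structure.

The generator emulates the study conditions: 73 infants, sequence
truncation at the first look-away, session dropout calibrated so infants
watch about 7 of the 16 sequences on average, and three gaze measures
whose means track weighted information gain.
"""

import metagaze as mg

design = mg.generate_task_design(seed=1)
table = mg.simulate_cohort(design, seed=0)

print("infants simulated:", table.n_infants)
print("rows (attended trials):", len(table.frame))
print("mean sequences watched:", round(table.sequences_watched().mean(), 2))
print("mean trials per infant:", round(table.trials_per_infant().mean(), 1))
print("look-away rate per trial:", round(table.frame["look_away"].mean(), 3))

excluded = mg.apply_exclusion(table, min_trials=20)
print(
    f"\nexclusion (<20 trials): {excluded.n_excluded} of {table.n_infants} "
    f"infants dropped, {excluded.n_infants} analyzed"
)
print("\nfirst rows:")
print(excluded.frame.head(5).round(1).to_string(index=False))
print(
    "\nLatency and looking time are missing on look-away trials; a sequence"
    "\nnever continues past its first look-away."
)
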