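"""Generate the probabilistic cue-target task and its information-gain map.

Builds the default 16-sequence design (six 60%, six 80%, four 100%
predictable sequences of 15 trials each), checks its invariants, and runs
the ideal observer over it.
"""

import metagaze as mg

design = mg.generate_task_design(seed=1)
print("violations:", mg.validate_design(design))
print("per-location target counts:", design.location_counts(), "(of 240 trials)")
print("schedule:", [f"{s.high_prob:.0%}" for s in design.sequences])

trace = mg.info_trace(design)
pivot = trace.pivot()
print("\nIdeal-observer information gain (nats), first 5 trials:")
print(pivot.iloc[:, :5].round(4).to_string())
print(
    "\nTrial 1 always carries the same gain (%.4f nats): the uniform prior"
    % pivot[1].iloc[0],
    "\nmakes every first observation equally informative.  Fully predictable",
    "\nsequences decay fastest: repeated confirmation adds less and less.",
)
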