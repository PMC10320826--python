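"""Apply the meta-learning weighting kernel to the information-gain trace.

Shows how a positive late-down-weight slope (beta1) makes late-trial
information count less and less as the session progresses, while leaving
early trials nearly untouched -- the signature of meta-learning found in
infants.
"""

import metagaze as mg

design = mg.generate_task_design(seed=1)
trace = mg.info_trace(design)

downweight = mg.WeightingParams(lam0=1.0, lam1=0.0, beta0=0.1, beta1=0.065)
weighted = mg.weight_info(trace, downweight)
pivot = weighted.pivot()

print("Weighted information gain IG_{s,t} (beta1 = 0.065):")
print(pivot.iloc[[0, 4, 15 - 1], :6].round(4).to_string())
ratio = pivot.loc[16, 10] / pivot.loc[1, 10]
print(
    f"\nAt trial 10, sequence 16 retains {100 * ratio:.2f}% of the weight"
    " sequence 1 gives the same evidence:\nlate evidence in late sequences"
    " is treated as irrelevant."
)

for name in ("null", "upweight", "downweight", "full"):
    variant = mg.make_variant(name)
    print(f"variant {name!r}: free slopes {variant.free_params or '(none)'}")
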