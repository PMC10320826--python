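# metagaze

Hierarchical Bayesian modelling of how infants *learn to learn* from
probabilistic visual sequences, built around eye-tracking-style gaze data.

Infants watching sequences of cue–target trials extract not only where the
target tends to appear, but also *where in each sequence the useful
evidence lives*. `metagaze` implements a computational pipeline for that
question, for developmental and computational cognitive scientists:

1. **Task model** — a session of 16 sequences of 15 cue–target trials over
   K = 4 screen quadrants, with one high-likelihood quadrant per sequence
   (60%/80%/100% predictability, six/six/four sequences), an exact 25%
   per-quadrant target marginal, and a fully predictable first sequence.
2. **Ideal observer** — Dirichlet-categorical belief updating from a
   uniform prior, `P(X)_{s,t} = (X_{s,t} + γ)/(t + K)`, with trialwise
   information gain quantified as the KL divergence (nats) between
   consecutive predictive distributions.
3. **Meta-learning weighting kernel** —
   `IG_{s,t} = (λα0 + λα1·s)·exp(−t·(βα0 + βα1·s))·D_KL_{s,t}`:
   λα1 up-weights early-trial information across sequences, βα1
   down-weights late-trial information. Four variants (null / upweight /
   downweight / full) clamp the slopes.
4. **Inference engine** — one joint hierarchical model linking weighted
   information gain to three gaze measures (look-away, Bernoulli-logit;
   saccadic latency, Gaussian; looking time, Gaussian on log scale), with
   per-infant coefficient deviations, trial-number and baseline-attention
   covariates; sampled by the package's gradient-based dynamic HMC
   (no-U-turn) sampler; split-R̂/ESS diagnostics; −ELPD model comparison by
   LOO and WAIC.
5. **Synthetic cohort generator** — 73 infants, look-away truncation,
   session dropout calibrated to ≈ 7 sequences watched on average, and the
   three measures driven by weighted information gain, so the whole
   pipeline is testable end to end without any raw data.
6. **Reporting** — held-out-sequence re-weighting simulation, the
   latency-based learning-efficiency regression, figures and a manifest.

See `docs/methods.md` for the full model specification and design choices.

## Worked example

`examples/` contains one short script per capability. The core fit
(`examples/04_fit_weighting_model.py`) simulates a 24-infant cohort with
down-weighting on (βα1 = 0.065, λα1 = 0) and refits it:

```text
fitting full model to 16 infants, 1163 trials
max split-R-hat: 1.020 (converged: True)

posterior summary (94% HDI):
        mean     sd  hdi_low  hdi_high  different_from_zero
param
lam1   0.025  0.030   -0.016     0.076                False
beta1  0.093  0.021    0.057     0.134                 True
b_la  -8.439  2.896  -13.825    -3.292                 True
b_sl   1.064  0.485    0.258     1.919                 True
b_lt  -1.075  0.495   -2.056    -0.336                 True
```

Read: the late-down-weight slope βα1 is recovered as credibly positive
(its 94% HDI excludes zero and covers the generating 0.065), the
up-weight slope λα1 straddles zero (none was simulated), and the three
information-gain coefficients keep their generating signs — more
informative trials mean fewer look-aways, slower saccades and shorter
looking times on this cohort. The script then re-weights the held-out
16th sequence as if seen early vs late in the session: viewed as sequence
5 it starts at the same perceived information but loses it far faster
over trials than viewed as sequence 1 — down-weighting of late, irrelevant
evidence.

`examples/05_model_comparison.py` scores variants by −ELPD (the downweight
variant beats the null by ΔLOO ≈ 28 ± 7 on the same cohort, with LOO and
WAIC in close agreement), and `examples/06_learning_efficiency.py`
recovers a negative log-trial learning curve and a positive
sequence × trial interaction from latencies on predictable trials.

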