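# Methods

`metagaze` implements a computational account of how infants *meta-learn*
— how they change the way incoming evidence is weighted as they accumulate
experience with a structured environment — and the statistical machinery
needed to estimate and test that account from gaze data. This note records
the model, the choices that were genuinely open, and what the synthetic
data can and cannot show.

## Task model

The environment is a session of 16 sequences of up to 15 cue–target
trials. On each trial of sequence *s* the target appears in one of *K* = 4
screen quadrants, `x_{s,t} ∈ {1..4}`. One quadrant per sequence is the
high-likelihood location, hit on an exact 60%, 80% or 100% of trials
(9/12/15 of 15); six sequences are 60%-predictable, six 80% and four 100%.
Levels are exact within-sequence counts, not Bernoulli rates, because the
schedule is a fixed stimulus list shared by all participants. Across the
240 trials every quadrant is the target exactly 60 times, so location
identity carries no information; the generator solves this marginal
constraint exactly (greedy balanced assignment of high locations plus a
backtracking allocation of the off-trials, seeded). The first sequence is
always fully predictable; the remaining level order and all
within-sequence orderings are seeded permutations. Probabilistic sequences
always use at least two distinct low-probability locations.

## Ideal observer

Within each sequence the observer holds a Dirichlet-categorical belief
with uniform prior `γ = [1,1,1,1]`. After *t* observations the predictive
probability of location *i* is `(X_t[i] + 1) / (t + 4)`. Belief resets at
every sequence boundary (the shape of each sequence's information profile
restarts high), and *t* counts within-sequence observations only. The
information gain of a trial is the Kullback–Leibler divergence between the
posterior- and prior-trial predictive distributions, in nats:
`D_KL = Σ_i P_t[i] log(P_t[i]/P_{t-1}[i])`. Natural logarithms are used
throughout; the base only rescales the weighting intercepts and regression
coefficients.

## Meta-learning weighting kernel

Perceived information gain is the raw gain times a kernel in the sequence
index *s* and trial index *t* (both 1-based):

    IG_{s,t} = (λα0 + λα1·s) · exp(−t·(βα0 + βα1·s)) · D_KL_{s,t}

`λα1` captures progressive up-weighting of early-trial information across
sequences, `βα1` progressively stronger exponential down-weighting of
late-trial information. Four variants clamp the slopes: null (both 0),
upweight (λα1 free), downweight (βα1 free), full (both free); the
intercepts are free in all variants. The exponent is read as a decay
*rate* `βα0 + βα1·s` (so positive βα1 = faster decay in later sequences);
the alternative timescale reading `exp(−t/(βα0+βα1·s))`, under which the
slope's sign would mean the opposite, is available behind
`WeightingParams(rate_form=False)`. Validity (`λα0+λα1·s > 0`,
`βα0+βα1·s ≥ 0` over the design's range) is hard-checked in forward
evaluation and enforced by zero posterior density during inference.

## Observation model

One joint hierarchical model links the weighted gain to three per-trial
measures: look-away (Bernoulli with logit link), saccadic latency
(Gaussian on the z-scored millisecond scale) and looking time (Gaussian on
the z-scored log-millisecond scale, which keeps durations positive).
Before entering the model, `D_KL` is standardized to unit variance across
the design — a parameter-free, design-level constant — so the IG
regression coefficients are of order one (per SD of raw information gain).
Every linear predictor contains an intercept, the IG term, the centered
trial number, and a centered sequence-number term (linear baseline
attention drift, separating fatigue from meta-learning). The IG
coefficient of each measure is hierarchical: group mean plus per-infant
deviation with its own scale, in the non-centered parameterization. The
weighting parameters are group-level and shared across the three
measures, so all measures jointly inform them. Trials after a look-away
contribute nothing; the look-away trial itself contributes only to the
look-away likelihood.

Note one structural softness: λα0 multiplies every IG term, so it trades
off against the three IG coefficients (only the products are strongly
identified). The priors resolve the scale; the products — and the slopes
λα1, βα1, which drive the scientific conclusions — are well identified.

**Priors** (all hyperparameters exposed in `PriorSpec`): half-Normal(1)
for λα0, βα0, the residual scales and the subject-deviation scales;
Normal(0,1) for λα1, βα1 and the trial/attention slopes; Normal(0,2) for
intercepts; Normal(0,5) for the group IG coefficients (wide enough that
look-away effects of magnitude ≈ 5 per SD of IG are not shrunk).

## Inference

Posteriors are sampled with the package's own gradient-based MCMC: a
dynamic Hamiltonian Monte Carlo sampler (no-U-turn trajectory doubling
with multinomial proposal sampling, dual-averaging step-size adaptation to
a 0.85 target acceptance, diagonal mass-matrix adaptation during warmup,
divergence detection at an energy error of 1000). The joint density and
its analytic gradient are evaluated in a compiled single-pass kernel;
kernel terms are computed once per unique (sequence, trial) combination.
Two chains are required; split-R̂ < 1.05 for every parameter is the
convergence criterion, with R̂ and a Geyer initial-monotone-sequence ESS
computed from the stored draws. Desk-scale defaults are 2 chains × (800
warmup + 800 retained) draws; the acceptance and test runs use 350–600 of
each, and `FitConfig.study_scale()` configures a long-warmup two-chain run
(390,000 warmup, 10,000 retained). Summaries report posterior mean, SD and
the 94% highest-density interval (narrowest contiguous interval);
"different from zero" means the HDI excludes 0.

Model comparison scores each variant by −ELPD via Pareto-smoothed LOO and
WAIC (through arviz, from pointwise log likelihoods stored per measure),
per measure and in total; differences from the null variant carry a
paired-pointwise standard error.

## Synthetic cohort

The generator is the model run forwards under the study conditions: 73
infants; per-infant IG coefficients drawn around group means −4.98
(look-away logit), +0.69 (latency, z) and −0.57 (log looking time, z) with
spreads 1.0/0.15/0.15; kernel λα0 = 1, λα1 = 0, βα0 = 0.1, βα1 = 0.065
(down-weighting on, up-weighting off, matching the phenomenon the analysis
is built to detect); look-away base logit −1.5 with a small positive trial
slope and positive attention drift (fatigue); latency mapped as
400 + 150·z ms (negative values = anticipations are possible); looking
time as exp(log 1500 + 0.5·z) ms. A sequence truncates at its first
look-away. Sessions end between sequences with a constant hazard
h = 0.126, chosen in closed form so the expected number of sequences
watched, `(1 − (1−h)^16)/h`, is ≈ 7.0. Typical output: ≈ 7 sequences and
≈ 65 trials per infant, with ≈ 10% of infants falling under the 20-trial
exclusion.

What the generator does *not* emulate: raw gaze coordinates and fixation
classification, the 750 ms post-offset looking window (looking time is
generated directly as a trial summary), any dependence of fussiness on the
stimuli (dropout is exogenous, while real missingness is acknowledged to
be non-random in a richer way), and per-infant variation in the weighting
parameters themselves (estimated at the group level only, as in the
analysis). Passing tests therefore show that the pipeline recovers what it
assumes, under realistic sample sizes and missingness structure — not that
real infant data satisfy those assumptions.

A second, purpose-built generator (`simulate_latency_learning`) produces
latencies directly from the efficiency regression (below) with known
coefficients, with predictor centering computed on the realized
post-dropout sample so recovery is exact by construction.

## Learning-efficiency analysis

Saccadic latencies on predictable-location trials (the sequence's
high-likelihood quadrant), excluding each sequence's first trial, are
modelled as: centered sequence number + centered log within-sequence trial
number + their interaction + overall trial number, with per-infant random
intercepts and random slopes on every within-infant predictor
(hierarchical Gaussian regression, same sampler). The overall-trial
control is nearly collinear with sequence number; it is residualized
against the other predictors before fitting (identical column span, so the
substantive coefficients keep their "controlling for" interpretation,
while the posterior geometry improves markedly). Marginal effects of
sequence number are reported at each trial index as
`β_seq + β_interaction·(log t − mean log t)`, with the overall-trial
covariate held at its mean. A negative log-trial effect indicates
within-sequence learning; a positive interaction indicates faster learning
in later sequences.

## Held-out-sequence simulation

Given a fitted posterior, the last sequence's D_KL profile is re-weighted
as if the sequence had occurred at session position 1 vs 5 (configurable),
per posterior draw (≥ 500 draws; 95% credible bands). Under a posterior
with βα1 > 0 and λα1 ≈ 0 the position-5 curve starts level with the
position-1 curve and falls below it on later trials.

## Numerical and scaling choices

- Problem sizes: acceptance-style checks use n = 73 cohorts with 2 × (350–600
  warmup + 350–500 retained) draws; parameter recovery uses 5 seeded
  replicates; calibration uses 200 cohorts. These are the package's
  desk-scale defaults; all sizes are arguments.
- Seeds: every stochastic step takes an explicit seed; chain seeds derive
  from the fit seed; identical seeds give identical results.
- Degenerate inputs: empty gaze tables are rejected at model build;
  header-only tables read as valid empty tables; zero posterior-predictive
  draws return empty arrays; validation of designs never raises.
- Ties in the HDI are resolved by the narrowest-interval rule on sorted
  draws (via arviz).

## Known limitations

- The likelihood families and prior hyperparameters are stated defaults,
  not a claim about any particular infant dataset; `PriorSpec` exists so
  alternatives can be dropped in verbatim.
- λα0's scale is prior-resolved (see above); report products or fix λα0
  when absolute coefficient magnitudes matter.
- The dropout process is a calibrated stand-in; analyses sensitive to
  missingness mechanisms should not lean on it.
- The efficiency regression assumes Gaussian residuals on the standardized
  latency scale; heavy-tailed latency distributions would call for a
  robust likelihood.
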