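"""Synthetic infant-gaze cohort generator.

Generates per-trial gaze tables with the statistical structure the analysis
pipeline assumes: three dependent measures (look-away, saccadic latency,
looking time) whose means shift with meta-learning-weighted information
gain, sequence truncation at the first look-away, and whole-session dropout
("fussiness") calibrated so infants watch about 7 of the 16 sequences on
average.

The generative direction mirrors the observation model fitted by
:mod:`metagaze.inference`:

* information gain ``IG_{s,t}`` is the ideal observer's D_KL, standardized
  to unit variance across the design, multiplied by the weighting kernel;
* each infant i draws their three IG-regression coefficients around the
  group means with between-infant spread ``subject_sd``;
* look-away is Bernoulli with a logit-linear model in IG, centered trial
  number and centered sequence number (the baseline-attention drift);
* saccadic latency is Gaussian on a standardized scale, then mapped to
  milliseconds (negative values = anticipations are possible);
* looking time is Gaussian on the log-millisecond scale, so it is always
  positive.

On the trial where the infant looks away, latency and looking time are
missing and the sequence stops; dropout ends the whole session between
sequences with a constant per-sequence hazard.
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .observer import InfoTrace, info_trace
from .task import TaskDesign, validate_design
from .weighting import WeightingParams, kernel

GAZE_COLUMNS = (
    "infant_id",
    "sequence",
    "trial",
    "location",
    "look_away",
    "saccadic_latency_ms",
    "looking_time_ms",
)

#: Per-sequence geometric dropout hazard giving E[sequences watched]
#: = (1 - (1-h)^16)/h ~ 7.0 over a 16-sequence session.
DEFAULT_DROPOUT_HAZARD = 0.126


class CohortError(ValueError):
    """Raised for invalid cohort configurations or malformed gaze tables."""


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for a synthetic cohort.

    The IG coefficients act on the standardized information-gain scale and
    default to the group-level effects the analysis is designed to detect:
    strongly reduced look-away probability, slower saccades and shorter
    looking times for more informative trials.
    """

    n_infants: int = 73
    weighting: WeightingParams = field(
        default_factory=lambda: WeightingParams(lam0=1.0, lam1=0.0, beta0=0.1, beta1=0.065)
    )
    # group-level IG effects: look-away logit, saccadic latency (z), log looking time (z)
    coef_la: float = -4.98
    coef_sl: float = 0.69
    coef_lt: float = -0.57
    # trial-number covariate slopes (per centered trial)
    trial_slope_la: float = 0.05
    trial_slope_sl: float = -0.05
    trial_slope_lt: float = -0.05
    # baseline-attention drift across sequences (per centered sequence)
    attention_slope_la: float = 0.08
    attention_slope_sl: float = 0.02
    attention_slope_lt: float = -0.02
    lookaway_base_logit: float = -1.5
    # between-infant spread of the IG coefficients
    subject_sd_la: float = 1.0
    subject_sd_sl: float = 0.15
    subject_sd_lt: float = 0.15
    # measurement scales
    sl_baseline_ms: float = 400.0
    sl_scale_ms: float = 150.0
    lt_log_baseline: float = 7.31  # log(1500 ms)
    lt_log_scale: float = 0.5
    dropout_hazard: float = DEFAULT_DROPOUT_HAZARD

    def validate(self) -> None:
        if self.n_infants < 2:
            raise CohortError("n_infants must be >= 2")
        for name in ("subject_sd_la", "subject_sd_sl", "subject_sd_lt",
                     "sl_scale_ms", "lt_log_scale"):
            if getattr(self, name) <= 0:
                raise CohortError(f"{name} must be > 0")
        if not 0.0 <= self.dropout_hazard < 1.0:
            raise CohortError("dropout_hazard must be in [0, 1)")


@dataclass(frozen=True)
class GazeTable:
    """Per-trial gaze records plus provenance.

    ``frame`` holds one row per infant x sequence x attended trial with the
    columns in :data:`GAZE_COLUMNS`; missing latency/looking time (on
    look-away trials) are NaN.
    """

    frame: pd.DataFrame
    design: TaskDesign | None = None
    seed: int = -1
    config_hash: str = ""
    n_excluded: int = 0

    @property
    def n_infants(self) -> int:
        return self.frame["infant_id"].nunique()

    def sequences_watched(self) -> pd.Series:
        """Number of distinct sequences with at least one attended trial."""
        return self.frame.groupby("infant_id")["sequence"].nunique()

    def trials_per_infant(self) -> pd.Series:
        return self.frame.groupby("infant_id").size()


def config_hash(config: CohortConfig) -> str:
    return hashlib.md5(repr(config).encode()).hexdigest()[:12]


def scaled_dkl_frame(trace: InfoTrace) -> pd.DataFrame:
    """Trace frame with D_KL standardized to unit variance across the design.

    The scale is a design-level constant (no parameters involved), chosen so
    that regression coefficients on information gain are per standard
    deviation of raw D_KL and hence of order one.
    """
    frame = trace.frame.copy()
    frame["d_scaled"] = frame["d_kl"] / frame["d_kl"].std(ddof=0)
    return frame


def simulate_cohort(
    design: TaskDesign, config: CohortConfig | None = None, seed: int = 0
) -> GazeTable:
    """Simulate a cohort of infants watching the task.

    Deterministic given ``seed``.  Each infant watches sequences in order
    until the session drops out; within a sequence, trials run until the
    first look-away or the end of the sequence.
    """
    config = config or CohortConfig()
    config.validate()
    violations = validate_design(design)
    if violations:
        raise CohortError(f"design does not validate: {violations[0]}")

    trace = info_trace(design)
    scaled = scaled_dkl_frame(trace)
    n_seq = design.n_sequences
    # centered covariates shared with the fitting pipeline
    t_center = scaled["trial"].mean()
    s_center = scaled["sequence"].mean()

    ig = {}
    for snum, grp in scaled.groupby("sequence"):
        grp = grp.sort_values("trial")
        w = kernel(grp["sequence"].to_numpy(), grp["trial"].to_numpy(), config.weighting)
        ig[int(snum)] = {
            "ig": w * grp["d_scaled"].to_numpy(),
            "trial": grp["trial"].to_numpy(),
            "location": grp["location"].to_numpy(),
        }

    rng = np.random.default_rng(seed)
    rows = []
    for infant in range(1, config.n_infants + 1):
        b_la = config.coef_la + config.subject_sd_la * rng.standard_normal()
        b_sl = config.coef_sl + config.subject_sd_sl * rng.standard_normal()
        b_lt = config.coef_lt + config.subject_sd_lt * rng.standard_normal()
        for snum in range(1, n_seq + 1):
            seq = ig[snum]
            t = seq["trial"]
            t_c = t - t_center
            s_c = snum - s_center
            eta = (
                config.lookaway_base_logit
                + b_la * seq["ig"]
                + config.trial_slope_la * t_c
                + config.attention_slope_la * s_c
            )
            p_la = 1.0 / (1.0 + np.exp(-eta))
            la = rng.random(len(t)) < p_la
            n_watch = int(np.argmax(la)) + 1 if la.any() else len(t)
            mu_sl = (
                b_sl * seq["ig"]
                + config.trial_slope_sl * t_c
                + config.attention_slope_sl * s_c
            )
            mu_lt = (
                b_lt * seq["ig"]
                + config.trial_slope_lt * t_c
                + config.attention_slope_lt * s_c
            )
            z_sl = mu_sl + rng.standard_normal(len(t))
            z_lt = mu_lt + rng.standard_normal(len(t))
            sl_ms = config.sl_baseline_ms + config.sl_scale_ms * z_sl
            lt_ms = np.exp(config.lt_log_baseline + config.lt_log_scale * z_lt)
            for k in range(n_watch):
                looked_away = bool(la[k])
                rows.append(
                    (
                        infant,
                        snum,
                        int(t[k]),
                        int(seq["location"][k]),
                        int(looked_away),
                        np.nan if looked_away else float(sl_ms[k]),
                        np.nan if looked_away else float(lt_ms[k]),
                    )
                )
            if rng.random() < config.dropout_hazard:
                break  # fussy: session over

    frame = pd.DataFrame(rows, columns=list(GAZE_COLUMNS))
    return GazeTable(
        frame=frame,
        design=design,
        seed=seed,
        config_hash=config_hash(config),
    )


def apply_exclusion(table: GazeTable, min_trials: int = 20) -> GazeTable:
    """Drop infants who attended fewer than ``min_trials`` trials in total."""
    counts = table.trials_per_infant()
    keep = counts[counts >= min_trials].index
    excluded = int((counts < min_trials).sum())
    frame = table.frame[table.frame["infant_id"].isin(keep)].reset_index(drop=True)
    return replace(table, frame=frame, n_excluded=table.n_excluded + excluded)


def simulate_latency_learning(
    design: TaskDesign,
    n_infants: int = 73,
    beta_trial: float = -0.45,
    beta_sequence: float = 0.0,
    beta_interaction: float = 0.04,
    beta_overall: float = 0.0,
    subject_sd: float = 0.1,
    sigma: float = 0.8,
    sl_baseline_ms: float = 400.0,
    sl_scale_ms: float = 150.0,
    dropout_hazard: float = DEFAULT_DROPOUT_HAZARD,
    seed: int = 0,
) -> GazeTable:
    """Cohort whose saccadic latencies follow the learning-efficiency model.

    Latencies on predictable-location trials are generated directly from the
    regression the efficiency analysis fits: a log-trial learning curve
    (``beta_trial``), a sequence effect, their interaction (positive values
    give faster early-trial latencies in later sequences, the meta-learning
    signature) and an overall-trial drift, with per-infant random slopes of
    spread ``subject_sd`` on every predictor and residual scale ``sigma``
    (all on the standardized-latency scale).  Sessions end early with the
    same per-sequence dropout hazard as :func:`simulate_cohort`; look-away
    and looking time are not modelled here.
    """
    rng = np.random.default_rng(seed)
    recs = []
    for s in design.sequences:
        for t, loc in enumerate(s.trial_locations, start=1):
            if t >= 2 and loc == s.high_prob_location:
                recs.append((s.sequence_number, t, loc))

    # realized attendance first, so predictor centering matches the sample
    # the analysis will actually see (coefficients are defined on the
    # analyzed scale: pooled-centered sequence and log-trial)
    n_seq = design.n_sequences
    rows = []
    for infant in range(1, n_infants + 1):
        last_seq = n_seq
        for snum in range(1, n_seq + 1):
            if rng.random() < dropout_hazard:
                last_seq = snum
                break
        for snum, t, loc in recs:
            if snum <= last_seq:
                rows.append((infant, snum, t, loc))
    arr = np.array(rows, dtype=float)
    infant_col = arr[:, 0].astype(int)
    seq = arr[:, 1]
    tri = arr[:, 2]
    seq_c = seq - seq.mean()
    logt_c = np.log(tri) - np.log(tri).mean()
    overall = np.concatenate(
        [np.arange(1, c + 1, dtype=float) for c in np.bincount(infant_col)[1:]]
    )
    overall_z = (overall - overall.mean()) / overall.std()
    X = np.column_stack([np.ones(len(arr)), seq_c, logt_c, seq_c * logt_c, overall_z])
    betas = np.array([0.0, beta_sequence, beta_trial, beta_interaction, beta_overall])

    b_i = betas[None, :] + subject_sd * rng.standard_normal((n_infants + 1, len(betas)))
    z = np.einsum("ij,ij->i", X, b_i[infant_col]) + sigma * rng.standard_normal(len(arr))
    sl = sl_baseline_ms + sl_scale_ms * z
    frame = pd.DataFrame(
        {
            "infant_id": infant_col,
            "sequence": seq.astype(int),
            "trial": tri.astype(int),
            "location": arr[:, 3].astype(int),
            "look_away": 0,
            "saccadic_latency_ms": sl,
            # looking time is not simulated here; column kept for schema
            "looking_time_ms": np.nan,
        }
    )
    return GazeTable(frame=frame, design=design, seed=seed)


def _check_invariants(frame: pd.DataFrame) -> None:
    for col in GAZE_COLUMNS:
        if col not in frame.columns:
            raise CohortError(f"gaze table missing column {col!r}")
    for (infant, seq), grp in frame.groupby(["infant_id", "sequence"]):
        grp = grp.sort_values("trial")
        la = grp["look_away"].to_numpy()
        if la[:-1].any():
            row = grp.index[int(np.argmax(la))]
            raise CohortError(
                f"row {row}: look_away=1 at infant {infant} sequence {seq} "
                "is followed by later trials (truncation invariant violated)"
            )
        la_rows = grp[grp["look_away"] == 1]
        for col in ("saccadic_latency_ms", "looking_time_ms"):
            bad = la_rows[la_rows[col].notna()]
            if len(bad):
                raise CohortError(
                    f"row {bad.index[0]}: column {col!r} present on a "
                    "look-away trial"
                )


def write_gaze_table(table: GazeTable, path) -> None:
    """Write the table as delimited text; missing values as empty fields."""
    table.frame.to_csv(path, index=False)


def read_gaze_table(path, design: TaskDesign | None = None) -> GazeTable:
    """Read a gaze table, enforcing the truncation/missingness invariants."""
    frame = pd.read_csv(path)
    if len(frame) == 0 and set(GAZE_COLUMNS) <= set(frame.columns):
        return GazeTable(frame=frame, design=design)
    _check_invariants(frame)
    if design is not None:
        loc_map = {
            (s.sequence_number, t): loc
            for s in design.sequences
            for t, loc in enumerate(s.trial_locations, start=1)
        }
        for r in frame.itertuples():
            expected = loc_map.get((int(r.sequence), int(r.trial)))
            if expected is not None and int(r.location) != expected:
                raise CohortError(
                    f"row {r.Index}: column 'location' = {r.location} does not "
                    f"match the design ({expected}) at sequence {r.sequence} "
                    f"trial {r.trial}"
                )
    return GazeTable(frame=frame, design=design)
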