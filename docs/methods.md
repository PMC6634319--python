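# Methods

`pupilmw` implements an event-locked pupillometry analysis of mind wandering
(MW) triggered by task-irrelevant verbal cues, together with a synthetic-data
generator that emulates the probe-caught vigilance paradigm the analysis was
designed for. This note documents the generative model, the preprocessing and
epoching conventions, the statistical machinery, and the design choices made
where the problem was genuinely open.

## The paradigm being emulated

A participant watches 1120 two-second trials of white bars on a black screen
(68 vertical-bar targets among horizontal-bar non-targets, targets separated
by 9–31 trials) and presses a key for targets. On 210 trials a short verbal
cue (70 neutral, 70 positive, 70 negative) appears under fixation. At 28
fixed points (mean separation exactly 40 trials, counted from session start;
SD of the sampled gaps near 7.5) the task halts and a thought-probe asks what
the participant was thinking immediately before, whether the thought was
spontaneous or deliberate, and what triggered it (a word on screen, their own
thoughts, the environment, or nothing). Pupil diameter is recorded
binocularly at 30 Hz in millimetres.

Two generator-level co-occurrence rules are imposed that the task
description leaves open: cue-words never appear on target trials, and probes
never directly follow a target trial. Both avoid conflating the strong
light responses of targets/words with the event-locked selections.
Cue-words are not placed uniformly: the 4th trial before a probe carries a
cue with probability `p_cue_before_probe` (default 0.75, the level the
confound check reports for the original fixed sequence), and the remaining
cues fill the other non-target trials uniformly.

## Generative model

**Latent states.** Each probe's report category is drawn i.i.d. from a
mixture whose defaults are the published per-subject report rates out of 28
probes: on-task 7.36/28, spontaneous MW 9.57/28, intentional MW 2.10/28, the
remainder split evenly across external distraction, task-related thought and
blank mind. Every MW report is backed by a contiguous latent episode ending
at the pre-probe trial; episodes never span an earlier probe. Spontaneous
episodes are cue-triggered with probability 212/402 (the published fraction);
the trigger cue is drawn from the cues shown since the previous probe, with
exponential lag-weights solved by bisection so the conditional expected
trigger-to-probe lag equals `trigger_lag_mean_trials` (default 9) whenever
the realized cue placements allow it. Windows without a cue near the probe
force longer lags, so the realized ensemble mean sits slightly above the
target (≈ 9.3 trials at defaults, against a published mean of 8.97); we
accept this structural excess rather than distort the per-window
distribution. Cue-triggered episodes begin on the trial *after* the cue (the
word is read during its own trial); other episodes have geometric durations
(mean 6 trials — the source reports no duration distribution, so this is an
exposed parameter, not a literature value). Reports are re-derived from the
latent trace by a pure function, so reports and states can never disagree.

**Pupil signal.** The trace is additive, in mm:

    y(t) = baseline − Σ_onsets a·h(t − t_onset) + d(t) + AR(1) + white noise

with `h(t) = (t/t_max)^n · exp(n(1 − t/t_max))`, the gamma-family pupillary
impulse response with unit peak at `t_max` (defaults n = 10.1,
t_max = 0.93 s, the standard pupillometry parameterization). Every trial
onset contributes a bar constriction (default 0.10 mm); word trials add a
larger word constriction (default 0.25 mm). The MW dilation `d(t)` ramps
linearly over `mw_ramp_s` (default 2 s, one trial) from episode onset to the
episode's amplitude (default 0.10 mm, with 0.02 mm between-subject SD),
holds to the episode offset, and ramps down symmetrically. Noise is an AR(1)
process (stationary SD 0.02 mm, coefficient 0.97 at 30 Hz) plus white
measurement noise (SD 0.01 mm), independent per eye over a shared signal.
Samples are stamped at bin centres, (k + ½)/30 s, so the 20 Hz analysis grid
lies strictly inside the sampled range and linear signals are reconstructed
exactly.

**Artifacts.** Blinks (12/min, 0.2 s) and binocular tracker dropouts
(1.2/min, 1.5 s) mark samples invalid in both eyes and depress the flanking
samples by ~1–1.5 mm while leaving them flagged valid — exactly the shape
the percentile rejection stage must catch. At these defaults the >60% rule
excludes ≈ 3% of trials, the same order as the 4.45% reported for the real
recordings (logged by QC, not asserted).

**Behaviour.** Key presses are Bernoulli per trial with miss probability
0.33/68 and false-alarm probability 0.79/1052, reproducing the published
per-session expectations (0.33 misses, 0.79 false alarms).

**Seeding.** One master seed drives everything. The schedule stream is
derived from the master seed; subject *i*'s state/pupil/behaviour streams are
derived from (seed, i, stream-id) folded into a 31-bit integer. All subjects
share the fixed trial schedule, as in the original task.

## Preprocessing

Per 2-s trial, independently (no cross-trial interpolation):

1. **Eye combination** — per-sample mean of the valid eyes; a sample is lost
   only when both eyes are invalid.
2. **Percentile rejection** — samples strictly outside the trial's central
   90% interval (below the 5th or above the 95th percentile of its valid
   samples, linear-interpolation percentile definition, boundaries kept) are
   masked. The central two-sided variant is the default because blinks
   produce both low outliers (occlusion) and high ones (recovery overshoot);
   an `upper_90` one-sided variant is available. Hardware validity is never
   altered by masking, which makes the operation idempotent.
3. **Interpolation** — retained samples are linearly interpolated onto the
   fixed 40-point 20 Hz grid at 0.025 + k·0.05 s; edge gaps take the nearest
   retained value.
4. **Exclusion** — a trial is excluded when more than 60% of its 60 raw
   time-points are lost (strictly greater; exactly 60% is retained).

The session-level path is vectorized (sort-based row percentiles,
index-bracketed interpolation) and is tested to agree with the per-trial
reference operations to machine precision.

## Epoching and labels

**Cue classes.** A cue is an *MW trigger* if a later probe names it as the
trigger of a spontaneous-MW episode; an *emotional non-trigger* if it is
positive/negative, unnamed, and the nearest following probe reports on-task;
*control* if it is neither an MW trigger nor an emotional cue whose nearest
following or preceding probe reports on-task; everything else (intentional-MW
triggers, emotional cues preceded but not followed by on-task) is excluded.
"Followed/preceded by an on-task period" is operationalized as the nearest
probe — the minimal reading of an underspecified rule; the resulting class
sizes are therefore not comparable to the original study's counts.

**Cue-aligned epochs** cover positions 0, 1, 2 (the cue trial and the two
following). Baseline = mean diameter over all 40 grid points of the cue
trial; all three trials must survive QC. Scalar summaries average the *last*
second (grid indices 20–39) of each trial, the half farthest from the
reference.

**Probe-aligned epochs** cover positions 3, 2, 1 before the probe (1 = the
trial immediately preceding it, which supplies the baseline); all three
trials must survive QC. Conditions are MW (spontaneous only), OT, and
"other" (including intentional MW). Summaries average the *first* second
(grid indices 0–19).

**Light responses** measure the bar-evoked constriction of a single trial:
mean over 0.5–1.0 s (grid 10–19) of the trace minus its first-250 ms mean
(grid 0–4). Candidates are dropped if the trial or its predecessor carries a
cue-word (which would shift the baseline), or fails QC. Two selections:
last trial before each MW/OT probe, and every target trial versus the last
non-target trial before it.

A confound check computes, per subject and report category, the probability
that a cue occupies the 4th trial before a probe, with across-subject mean
and standard error.

## Inference

**Model.** Epoch summaries pool across subjects at trial level and enter a
linear mixed model with fixed effects condition × position (treatment coding,
reference = control/other; position continuous) and a per-subject random
intercept:

    y_ij = x_ij'β + u_j + e_ij,  u_j ~ N(0, σ²_u),  e_ij ~ N(0, σ²_e).

Estimation profiles the likelihood over θ = σ²_u/σ²_e: β and σ²_e are
closed-form GLS at each θ via the per-group Woodbury identity, leaving a
1-D bounded optimization over log θ plus an explicit θ = 0 boundary check.
ML is the default (REML available). The fit is validated against
statsmodels' MixedLM on random datasets and degenerates exactly to OLS at
the boundary.

**F tests** are Wald tests with the residual-df convention: denominator
df = N − p, fixed-effect covariance scaled by r'V⁻¹r/(N − p). This is the
convention that reproduces the published df arithmetic — a three-condition
interaction on n₁+n₂+n₃ epochs × 3 positions has df (2, 3(n₁+n₂+n₃) − 6) —
and makes every F equal its OLS partial-F when σ²_u = 0. Post-hoc contrasts
refit the two conditions at a single position (intercept + indicator, random
intercept retained), giving df = n − 2. The split-half reliability analysis
splits epochs by within-subject ordinal parity (first-appearance order), so
halves differ by at most one epoch per subject, and refits each half
identically. No multiple-testing correction is applied (raw post-hoc p
values, as in the source analysis).

**Bayes factor.** The two-sample comparison is supplemented by a JZS Bayes
factor: Cauchy prior with scale r = √2/2 on the standardized effect,
equivalent to mixing g ~ InverseGamma(½, r²/2), with the marginal likelihood
ratio integrated by adaptive quadrature on the log-g scale (relative
tolerance 1e-10; an unreliable quadrature raises rather than falling back).
It is tested against a fixed 200k-point Simpson oracle to 1e-6 relative and
cross-checked against pingouin.

## Numerical and testing choices

- Problem sizes: parameter recovery and power use 200 simulated 42-subject
  cohorts at default parameters; type-I calibration uses 2000 six-subject
  cohorts on a structurally identical shrunken design (160 trials, 8
  targets, 30 cues, 4 probes); the light-response null check uses 12
  42-subject cohorts.
- The ground-truth cue-aligned slope contrast implied by the generator is
  0.5·d (effect profile 0, 0.75 d, d over positions 0–2 after baseline
  correction, whose least-squares slope is d/2), i.e. 0.05 mm/trial at the
  default 0.1 mm dilation.
- The interaction test is slightly conservative on pipeline data (epoch-level
  baseline noise is shared across a trio of observations, inflating the
  pooled residual variance relative to the slope contrast's true sampling
  variance); its empirical type-I rate at α = 0.05 remains ≈ 0.04.
- Degenerate inputs: zero-variance residuals are floored inside the profile
  log-likelihood only (estimates are untouched); a rank-deficient fixed
  design raises; a two-sample t with zero pooled variance returns t = 0,
  p = 1 for equal means and raises otherwise.
- Determinism: the bounded scalar optimizer uses a fixed tolerance
  (xatol 1e-10); CSVs are written with a fixed float format so identical
  runs are byte-identical.

## What the generator does not emulate

Gaze position and its calibration, luminance/photometric display modelling,
the semantic/affective norms of real Italian cue-words, pupil foreshortening,
meta-awareness of MW, and any dependence of task performance or light-reflex
gain on attentional state (the light-reflex gain during MW is an explicit
parameter, default 1 — i.e. no perceptual decoupling — so the light-response
comparison is a true null under defaults). Passing tests therefore
demonstrate the pipeline's correctness and calibration on data with known
ground truth, not the physiological reality of any particular effect size.

## Known limitations

- Report categories are i.i.d. across probes; real reports show serial
  dependence and time-on-task drift.
- The emotional non-trigger class under the nearest-probe reading is much
  larger than in the original data, where the (unstated) window was
  evidently narrower; between-class inference is unaffected but class
  counts are not comparable.
- MW dilation is a deterministic ramp-plateau; real dilation dynamics vary
  across episodes.
- The residual-df F convention is anti-conservative in principle for small
  subject counts; it is used deliberately for fidelity to the published
  analysis rather than Satterthwaite/Kenward–Roger approximations.
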