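# Methods

This note documents the models, defaults and numerical choices behind
`wristrhr`, and what the synthetic-data studies do and do not demonstrate.

## RHR derivation

A participant's device RHR is estimated from the PPG interbeat intervals
(IBIs) inside a 2-minute window `[mid − 60 s, mid + 60 s)` centered on the
midpoint of the ECG acquisition. Membership is half-open and judged by the
beat's end timestamp. The gating filters run in a fixed order:

1. **Wear gating.** A wrist-state record's value holds until the next record,
   so the records "overlapping" the window are those inside it plus the
   latest one at or before the window start. Any off-wrist record excludes
   the window (`excluded_off_wrist`); no overlapping record at all excludes
   it too (`excluded_no_wrist_data`) — absence of wear evidence is treated
   conservatively.
2. **Quality labels.** The jump distance of IBI *i* is `|I_i − I_{i−1}|`
   within a contiguous run (consecutive timestamps differing by exactly the
   IBI, ±0.5 ms). Labels are *good* when the jump is strictly below 100 ms;
   the first IBI of each run (undefined jump) is labeled good, a
   retention-conservative convention affecting at most one beat per run.
   Labels are computed on the full in-window run **before** any removal, so
   deletions cannot manufacture spurious jumps.
3. **Activity gating.** An IBI is dropped when its timestamp falls in a
   30-second actigraphy epoch with a nonzero count ("Active"), or in a span
   with no epoch coverage (stillness cannot be confirmed).
4. **Bad-quality removal**, then the **minimum-evidence rule**: fewer than 3
   surviving IBIs excludes the participant (`excluded_low_ibi`). Otherwise
   `RHR = 60000 · N / Σ I_i` bpm — the reciprocal of the mean retained
   interval, reported unrounded.

The jump-distance threshold (100 ms) and the minimum IBI count (3) are
exposed as parameters. The analysis cohort additionally requires an ECG
reading graded Excellent or Good; the exclusion-flow table accounts for every
participant (cohort + Σ exclusions = input).

Mean daily steps are averaged over calendar days 1–30 after enrollment,
keeping only days with ≥ 600 wear minutes (≥ comparison); the metric is
absent when no day qualifies.

## Agreement statistics

ICC(2,1) — two-way random effects, absolute agreement, single measure — is
computed from the ANOVA mean squares of the n×2 participant-by-method table:
`(MSR − MSE) / (MSR + MSE + (2/n)(MSC − MSE))`. This form is the standard
choice for two-device agreement; it penalizes systematic offsets, unlike
consistency ICCs. Bias is `mean(device − ECG)`; proportional error is the
OLS slope of the difference on ECG RHR (the reference, not the Bland–Altman
mean). Confidence intervals are seeded percentile bootstraps over
participants (default 1000 resamples, 95%, two-sided); degenerate resamples
are redrawn with a cap of 10× the replicate count. Subgroup analyses repeat
everything per sex.

## Trend analysis

Within each sex, device RHR is cut at the 25th and 75th percentiles using
type-7 (linear-interpolation) quantiles; assignment is `low: rhr ≤ c25`,
`mid: c25 < rhr ≤ c75`, `high: rhr > c75`. Categorical covariates are
expanded to a full set of level-vs-all-others dummies for testing (no
reference dropped). Binary covariates use the Cochran–Armitage trend
statistic with equally spaced scores (0, 1, 2) and no continuity correction;
continuous covariates use Spearman rank correlation against the ordinal
category with average ranks for ties. Tests run on complete cases with
two-sided p-values and no multiplicity adjustment (exploratory tables).
Note that the normal-approximation p is compared against an *exact
permutation mid-p* in the tests: on a lattice-coarse small table the raw
discrete tail and the asymptotic p differ by the boundary mass, and the
mid-p convention is the principled discreteness correction.

## Association models

Per sex stratum, the full covariate table (all domains, with age and device
RHR as auxiliary predictors) is multiply imputed by chained equations with
type-0 predictive mean matching: for each missing cell a linear model on the
other variables ranks observed cases by predicted-value distance and the
value is drawn uniformly from the 5 nearest donors; 10 chained sweeps per
chain, m = 5 independent chains, singular models fall back to a ridge fit.
Categoricals are integer-coded before imputation so imputed codes are always
observed levels, and decoded afterwards. "5 rounds" of imputation is read as
m = 5 completed datasets (standard multiple-imputation vocabulary); both m
and the sweep count are configurable.

Per (domain, sex) model: continuous vitals/physical-function and laboratory
measures are Box–Cox transformed (λ maximizing the profile log-likelihood on
a grid over [−2, 2] in steps of 0.01, with a `1 − min` shift for nonpositive
values); raw age and age² are appended to every domain's candidates (age² on
the raw scale, before standardization); categoricals are dummy-coded dropping
the most frequent level; all predictors are standardized. The m completed
tables are stacked vertically with observation weight 1/m (so the effective
sample size equals the number of participants), and a single elastic-net
objective is minimized by coordinate descent over a 100-point λ path spanning
4 decades down from λ_max, for α ∈ {0.5, 1}. Cross-validation uses 5 folds
assigned at the participant level — all m copies of a participant share a
fold — preventing leakage between copies of the same person; the (α, λ) pair
minimizing CV MSE is refit on the full stack. The outcome is device RHR in
bpm, centered within the stratum and not otherwise transformed. Coefficients
are reported in bpm per SD of predictor and ranked by magnitude; no
inference (CIs/p-values) is attached to penalized estimates.

## Synthetic cohort generator

The generator's defaults are the study conditions the pipeline is designed
for: 875 participants, 59.3% female; latent RHR marginals 66.6 (SD 11.2) bpm
for females and 64.4 (SD 12.3) bpm for males; ages uniform on 18–84 years.

* **Age profile.** Latent RHR = sex mean + `age_curvature · (age − 50)²`
  (centered within sex; default curvature −0.004 bpm/yr², an inverted U with
  a mid-life vertex), with the Gaussian residual scaled so the marginal SD
  hits its target exactly in the population.
* **ECG reference.** Latent RHR + N(0, 2.7 bpm). The default reference noise
  was chosen so the default cohort's ICC lands in the mid-0.9s, the regime
  typical of wrist-vs-ECG agreement studies.
* **Device layer.** Beats are emitted at `60000 / device RHR` ms with
  N(0, 30 ms) beat-to-beat jitter, quantized to integer milliseconds;
  timestamps are exact cumulative sums, so elapsed time is conserved. With
  per-beat probability `artifact_rate · (IBI/1000)^coupling` a beat is split
  into two near-halves (fractions U(0.45, 0.55)). The jump-distance filter
  catches the transition beats but the second of two similar half-beats
  survives, shortening the retained mean interval — a positive device bias
  that grows with IBI length, hence declines with reference RHR (negative
  difference-vs-reference slope) when the coupling is positive. Defaults:
  rate 0.03, coupling 2.
* **Clean injection knobs.** `device_offset_bpm` and `device_slope` shift the
  latent device RHR additively and proportionally to (latent − configured
  cohort mean). Parameter-recovery studies set the ECG reference noise to
  zero so the injected offset/slope is exactly the estimand of the
  difference-vs-ECG regression; with reference noise e the population slope
  of (device − ECG) on ECG would be contaminated by a −var(e)/var(RHR) term.
* **Gating streams.** On-wrist records every 60 s and 30-second epochs with
  background activity probability 0.05 per epoch; induced exclusions
  (off-wrist record in-window, all-active window, sparse IBI stream) are
  drawn per participant and recorded in the ground-truth table.
* **Covariates.** ~29 covariates across the five domains, with logistic
  links for binaries, linear-Gaussian (log-linear for skewed labs) forms for
  continuous measures, effect sizes per bpm of latent RHR, and MCAR
  missingness (default 5%). Default prevalences/means are realistic values
  for a middle-aged ambulatory cohort; the signed defaults plant the
  association directions the pipeline should detect (smoking, BMI, CRP,
  diabetes, disability score positive; six-minute-walk negative;
  unemployment the strongest demographics signal).

**What the generator does not emulate:** circadian heart-rate dynamics, raw
PPG waveforms and real peak-detection failure modes, informative
missingness, repeated visits, or between-covariate correlation beyond the
shared RHR link. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration under a plausible generative model, not the
field performance of any device.

## Problem sizes and numerics

Simulation-based tests run at the sizes their claims need: marginal
calibration at n = 5000, artifact-mechanism signs at n = 2000, bootstrap
coverage over 200 cohorts of n = 875, trend-test calibration over 1000
replicates of n = 500, selection recovery over 50 replicates of n = 500, and
one full n = 875 pipeline run (10 domain×sex models, m = 5, 1000 bootstrap
replicates). Tie-breaking in the CV grid prefers the first minimum scanned
(λ descending, α = 0.5 before 1). Degenerate inputs are flagged rather than
silently handled: constant RHR distributions put everyone in the low
category with a warning, constant Box–Cox inputs fall back to identity,
zero-variance references make the slope a data error.

## Known limitations

* The wrist-state "overlap" convention assumes states persist until the next
  record; sparse wrist streams therefore inherit the last pre-window state.
* PMM uses a fixed donor count (5) and type-0 matching; fully Bayesian
  parameter draws are not implemented.
* The elastic-net active-set size is only guaranteed monotone in λ on
  orthogonal designs; the property test uses one.
* Trend tables are unadjusted; no age adjustment is applied to the
  stratified descriptive comparisons.
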