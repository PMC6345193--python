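# Methods notes

This note documents the models implemented in `spantraj`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## The adaptive span task

Participants repeat aurally presented word sequences in order. The
engine implements the adaptive administration as a deterministic
function of the responder's correct/incorrect decisions:

* sequence lengths lie in [2, 8] words; administration starts at 3;
* two *calibration* items adapt after every item (+1 word if correct,
  −1 if not, clamped at the bounds);
* eight *test* items adapt after every completed pair: +1 if both
  correct, −1 if both incorrect, unchanged if split;
* points per item: sequence length if correct, length − 1 otherwise;
* the condition's span score is the mean of the eight test-item points.

Modelling decisions where the task description leaves room:

* **Start length.** Not fixed by the task description; the default of 3
  is a mid-low start appropriate for testing children from age 6 with a
  floor of 2, and is configurable.
* **Calibration feeds the test phase.** The test items start at the
  length reached after the second calibration adaptation — calibration
  would be pointless otherwise.
* **Correctness is binary** (strict serial order), with no partial
  credit, matching the span definition the scoring rule presupposes.
* **Clamping counts as adaptation**: at the floor/ceiling the staircase
  stays put rather than skipping items.
* Stimulus content (word identities, which of the 11 recorded sequences
  per length is played) never affects scoring and is carried only as
  metadata; a pool overrun triggers a warning, not an error.

**Score range.** `enumerate_score_range` replays all `2^10 = 1024`
response patterns. With the defaults the attainable range is
[1.0, 6.5]: an all-incorrect run floors at 1.0, an all-correct run walks
5,5,6,6,7,7,8,8 for a mean of 6.5. A theoretical maximum of 7.5 is
sometimes quoted for this task family, but no integer start length
reproduces it under the stated rules (all-correct runs yield 6.5, 7.25,
7.75 for starts 3, 4, 5); the package therefore reports the enumerated
ceiling rather than forcing that figure.

## The synthetic cohort

No raw participant data are available, so the generator produces
cohorts with the *statistical structure* the analysis assumes. It is a
stand-in, not a claim about real children.

* **Responder.** `P(correct | length L) = 1/(1 + exp((L − θ)/s))` with
  one latent span θ per condition and steepness `s = 0.5` words. Any
  smooth monotone link would serve; the logistic is the simplest with a
  tunable steepness. Expected span score is monotone in θ (verified by
  simulation).
* **Developmental indicators.** Chronological age (months), cognitive
  capacity and vocabulary raw scores are drawn per group from truncated
  trivariate normals. Defaults follow the published cohort descriptives
  (MBID: age 155 ± 30 months on [88, 205], COG 63.7 ± 13.2,
  VOC 53.1 ± 15.9; TD: age 101 ± 22 on [72, 161], COG 65.4 ± 13.5,
  VOC 54.7 ± 14.6; raw-score bounds [20, 100] and [5, 95], the latter
  being the vocabulary test's item count). Truncation attenuates
  correlations and shifts moments, so the sampler calibrates *latent*
  means/SDs/correlations by a cached, deterministically seeded
  fixed-point simulation until the realized truncated moments match the
  targets (MBID correlations 0.42/0.45/0.49, TD 0.74/0.73/0.67).
* **Measurement pattern.** Only 102 of the 123 TD children carry
  COG/VOC scores (the mental-age subsample); in the MBID group 7 lack
  COG and 7 others lack VOC, giving pairwise-complete ns of 80/80/73.
  Analyses exclude affected participants listwise per DI.
* **Latent trajectories.** θ = β₀(group, condition) + β₁(condition)·CA +
  N(0, 0.35). Slopes are shared across groups (a pure delayed-onset
  world) and rise from 0.009 to 0.016 words/month across conditions so
  that the word-length effect grows mildly with age. The intercepts were
  calibrated once by coarse search (iterating β₀ against simulated
  cohort means at n = 60,000) so the default cohort's condition means
  land within ±0.1 of the published cells; values are frozen in the
  preset. The preset is illustrative — it encodes one plausible world
  consistent with the published descriptives.
* **Order handling.** Length conditions run short before long for every
  participant; lexicality order is randomly assigned and recorded, but
  the generative model has no practice or fatigue effects, so scores do
  not depend on it.
* **Seeding.** One master seed is split into named substreams
  (indicators, sex, lexicality order, responders, trajectory noise,
  missingness), so identical seeds give identical cohorts.

What the generator deliberately does **not** emulate, and what that
means for the tests: real condition scores share a strong person-level
factor (published internal consistency ≈ 0.83); by default the
generator's condition residuals are independent, giving α ≈ 0.5. This
independence is what makes the ordinary-least-squares protocol's term
tests exactly nominal in the type-I simulations — passing those tests
shows the *inference machinery* is calibrated under its own assumptions,
not that real span data satisfy them. A `person_sd` shared ability
factor (default 0) can be switched on to mimic the higher internal
consistency; it induces within-participant correlation that plain OLS
ignores, which is precisely the repeated-measures caveat below. Dropout
(non-completion of pseudoword conditions) is not generated, though the
analysis side handles missing conditions listwise.

## Trajectory analysis

* **Outcome rows.** Capacity: one row per participant (mean of the four
  condition scores). Rehearsal/redintegration: two rows per participant
  (scores averaged over the other factor) with a centred task contrast
  (+0.5 = short / real), so the task main effect equals the effect in
  span units and the intercept is the grand mean.
* **Group coding.** TD = 0, MBID = 1: the `Group` coefficient is the
  MBID offset at the rescaled DI origin.
* **Rescaling.** Each DI is shifted so the *minimum MBID value* is 0;
  intercept comparisons therefore happen at the youngest/lowest observed
  MBID level instead of an extrapolated raw-score zero. Slopes and all
  interaction statistics are invariant to this shift (tested to 1e-8
  relative on F, 1e-6 absolute on p).
* **Protocol.** Step 1 `{1, DI}`; step 2 adds `{Group, Group×DI}`;
  step 3 `{Task, Task×DI}`; step 4 `{Task×Group, Task×Group×DI}`.
  Capacity has no task factor and stops at step 2.
* **Term tests.** Each term is tested by a drop-one nested comparison:
  partial F = ((RSS_r − RSS_f)/Δdf)/(RSS_f/df_f), partial
  η² = ΔRSS/RSS_r. With the centred contrasts and indicator group
  coding this behaves like a Type-III analysis; for single-df terms the
  partial F equals the squared coefficient t. α = 0.05, two-sided, no
  multiple-testing correction (raw p-values are reported).
* **Classification.** `delayed_onset` iff the intercept-difference term
  (`Group`, or `Task×Group` for task outcomes) is significant;
  `slowed_rate` iff the slope-difference term (`Group×DI` /
  `Task×Group×DI`) is; both → `combination`. The sign of the rate
  coefficient records whether the MBID slope is steeper or shallower.
* **Repeated measures.** The two rows per participant in task models are
  treated as independent observations, matching the cross-sectional
  trajectory protocol this package follows. Under the default generator
  (independent condition residuals) this is exactly valid; for data with
  person-level correlation a participant-clustered sandwich covariance
  is available (`cluster_robust=True`). It never changes estimates, only
  standard errors and p-values.
* **Per-group slope tests** regress the participant-level *effect score*
  on the DI within one group, giving F(1, n−2) with participant-level
  degrees of freedom; the slope estimate coincides exactly with the
  group's slope implied by the full-interaction fit (tested).
* **Sensitivity refits** take either an id list or a predicate (e.g.
  `cog_raw < 45`, the configured default rule for the cognitive-capacity
  trajectories), refit, and report excluded counts and significance
  flips.
* **Degenerate designs** (e.g. a DI constant within a group) raise a
  singular-design error naming the collinear columns rather than
  silently dropping terms.

### Descriptive statistics

The χ² test for the sex ratio applies Yates' continuity correction (the
convention of the statistics package the reference tables came from;
`correction="none"` gives plain Pearson), while φ is always
`sqrt(χ²_Pearson/n)` from the uncorrected statistic. The variance policy
for t tests is decided by a Levene pretest at α = 0.05 (`auto`), and
Cohen's d always uses the pooled SD, even when Welch's test is chosen.
"Internal consistency" of the four condition scores is computed as
Cronbach's α, the conventional statistic for a small fixed item set.

## Monte-Carlo validation

`run_recover` simulates full cohorts (engine administration included)
under four scenarios and classifies each replicate:

* `null` — both groups share the TD trajectory parameters;
* `onset` — MBID latent intercepts lowered by 0.4 words in every
  condition (slopes equal);
* `rate` — MBID slopes reduced by 0.012 words/month, with intercepts
  adjusted so the group lines cross at the expected rescaled DI origin
  (the 1/(n+1) quantile of the truncated MBID age marginal, ≈ 95
  months);
* `combined` — both.

The gap sizes were calibrated once for clear power at the default
sample sizes (87/123) and are frozen; with no published effect-size
ground truth they are package choices, not estimates. At 500 replicates
the null scenario rejects each classification term at the nominal 5%
within Monte-Carlo error for all three outcomes, the onset scenario is
labelled `delayed_onset` in ≈ 95% of replicates, and the rate scenario
`slowed_rate` in ≈ 85% with most of the remainder `combination`: because
the rescaling origin is the *sample* MBID minimum, which varies around
its expectation, a slope gap leaks slightly into the intercept term.
Default problem sizes (500 replicates for calibration tests, 100,000
draws for correlation-convergence checks, exhaustive enumeration of all
1024 staircase patterns) keep every check well-resolved while the whole
suite runs in about a minute.

## Known limitations

* Cross-sectional "trajectories" are correlations with (mental) age
  indicators, not longitudinal growth.
* The generator drives latent ability through chronological age only;
  trajectories against COG/VOC arise indirectly through the indicator
  correlations and are correspondingly attenuated.
* The logistic responder is a convenience; recovery results are
  conditional on this link.
* Proportional-scaling corrections of the word-length effect (relating
  the effect to overall performance level) are out of scope.
* Nonlinear or zero trajectories and linear-mixed-model variants of the
  protocol are not implemented.
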