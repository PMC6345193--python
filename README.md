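# spantraj

Adaptive word-span task simulation and cross-sectional
developmental-trajectory analysis of verbal working memory.

## What problem this addresses

In verbal working memory, two processes keep a fading phonological trace
alive: **rehearsal** (silent re-articulation, measured by the word-length
effect — short words are recalled better than long ones) and
**redintegration** (reconstruction of a degraded trace from long-term
lexical knowledge, measured by the lexicality effect — real words are
recalled better than pseudowords). A central question in research on
mild/borderline intellectual disability (MBID) is whether these processes
develop with a *delayed onset*, a *slowed rate*, or both, relative to
typically developing (TD) children.

`spantraj` is a tested, reusable implementation of the full analysis
chain for this kind of study, aimed at researchers in developmental
psychology and special education who want to simulate, power-check or
re-run such designs:

1. **Adaptive span-task engine** — a deterministic staircase: sequences
   of 2–8 words; two calibration items adapting after every item; eight
   test items adapting after every pair (+1 word if both correct, −1 if
   both incorrect); points = sequence length if correct, length − 1
   otherwise; span score = mean of the eight test-item points (so an
   all-incorrect run scores exactly 1).
2. **Synthetic cohort generator** — a logistic latent-ability responder
   (`P(correct) = 1/(1+exp((L−θ)/s))`) with θ linear in chronological
   age, plus group-specific truncated trivariate-normal developmental
   indicators (age, cognitive capacity, vocabulary) calibrated to the
   published descriptives and correlation structure of an 87 MBID /
   123 TD cohort.
3. **Effect scores** — phonological-loop capacity (mean of the 2×2
   condition scores), word-length effect and lexicality effect.
4. **Trajectory inference** — for each outcome × developmental indicator
   (DI), the nested four-step regression protocol

   `span ~ DI` → `+ Group, Group×DI` → `+ Task, Task×DI` →
   `+ Task×Group, Task×Group×DI`

   with the DI rescaled so the MBID minimum sits at 0, partial-F term
   tests with partial η², and classification of the group difference as
   `no_difference` / `delayed_onset` (intercept term) / `slowed_rate`
   (slope term) / `combination`, plus per-group slope tests and
   sensitivity refits under exclusion rules.
5. **Descriptives** — Student/Welch *t* with Cohen's *d*, χ²+φ for the
   sex ratio, per-group Pearson correlation matrices with
   pairwise-complete *n*s, Cronbach's α of the four condition scores.
6. **Monte-Carlo harness** — type-I and parameter-recovery simulation of
   the whole pipeline (engine included) under null / onset-gap /
   slope-gap generators.

## Worked example

```python
from spantraj import CohortConfig, simulate_cohort, DevelopmentalTrajectory

participants = simulate_cohort(CohortConfig(seed=1), return_trials=False)
model = DevelopmentalTrajectory.from_dataframe(participants,
                                               outcome="rehearsal", di="CA")
res = model.fit()
print(res.summary())
```

prints (abridged to the final step):

```
Developmental trajectory: rehearsal ~ CA (n obs = 420, excluded participants = 0)
...
Step 4: RSS = 47.2020, df = 412
  term                    coef        se         F         p  eta2_p
  const                 2.5772    0.0265
  DI                    0.0117    0.0010   133.836    0.0000   0.245
  Group                -0.8213    0.0677   147.233    0.0000   0.263
  Group:DI              0.0014    0.0013     1.160    0.2820   0.003
  Length                0.8172    0.0530   237.360    0.0000   0.366
  Length:DI             0.0031    0.0020     2.286    0.1313   0.006
  Length:Group         -0.3222    0.1354     5.665    0.0178   0.014
  Length:Group:DI       0.0015    0.0027     0.327    0.5676   0.001

Pattern: delayed_onset (onset term Length:Group: p = 0.0178; rate term
Length:Group:DI: p = 0.5676, MBID slope steeper)
```

Reading: the word-length effect (`Length`, +0.82 span units — short words
beat long words) is smaller in the MBID group at the rescaled age origin
(`Length:Group` = −0.32, p = 0.018: a **delayed onset** of rehearsal),
while its growth with age does not differ between groups
(`Length:Group:DI`, p = 0.57: no slowed rate). `res.classification`
carries the same verdict programmatically;
`res.fitted_effect_table()` returns the per-participant observed and
fitted effect values behind the trajectory scatterplots.

The same pipeline is available from the shell:

```sh
spantraj report --seed 1 --out results/run1      # simulate + analyse + descriptives
spantraj recover --scenario null --replicates 500 --seed 1
```

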