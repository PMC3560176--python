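# Methods

`actipheno` re-implements an objective adult-ADHD phenotyping analysis:
hyperactivity features extracted from infrared motion-capture trajectories,
attention/impulsivity features from two continuous-performance tasks, and a
four-stage discriminability comparison (per-measure effect sizes and ROC
areas, composite-index ROC comparison with DeLong tests, random-forest
variable importance, and cross-validated predictive modeling).  Because the
original subject-level data were never deposited, the pipeline runs on a
synthetic cohort whose per-group feature distributions are calibrated to
the published group means and 95% confidence intervals of a 40-case /
60-control study.  This note records the models, the calibration choices,
and what passing the test suite does and does not establish.

## Synthetic cohort

**From printed summaries to distributions.**  For each of the 36 measures
(12 movement, 12 star-task, 12 letter-CPT) the per-group standard
deviation is reconstructed from the printed 95% CI half-width,
`sd = (hi − lo)/2 / 1.96 · √n`, with the published sample sizes (n = 40
cases, 60 controls) and the normal multiplier (the published intervals are
z-style; at n ≥ 40 a t-quantile changes sd by < 1%).

**Marginal families.**  Approximately symmetric measures are normal.
Strictly positive, visibly skewed measures (immobility durations,
microevent counts, displacement, area, error counts, perseverations,
response bias) are moment-matched **gamma**; task accuracy, bounded above
at 100%, is a reflected gamma on the deficit `100 − accuracy`.  Gamma was
chosen over lognormal after checking both against the study's printed
per-measure ROC areas: with the reconstructed moments (group mean ratios
up to 6.5×), lognormal marginals imply between-group overlap that is too
small (e.g. shin immobility AUC 0.95 vs the printed 0.88), while gamma
marginals reproduce the printed AUCs closely.  Discrete measures are
rounded **stochastically** to their natural grid — counts to integers,
attention-state percentages to 2.5% (one of forty 30-s epochs).
Stochastic rounding is mean-preserving, and the resulting ties at zero are
what keep the rare-event measures (random/minimal %-time, perseverations)
near the chance-level ROC areas the study reports; no continuous marginal
can do this.

**Dependence structure.**  A standard-normal latent severity factor and
three domain factors (activity, star task, letter CPT; pairwise
correlation 0.3 through the shared severity) drive all measures via a
Gaussian copula.  Each measure's loading is proportional to its
latent-scale standardized group difference, expressed uniformly as
`√2·Φ⁻¹(AUC)` between the two group marginals, scaled so the largest
loading per domain is 0.95.  Proportionality matters: it guarantees that
linear contrasts orthogonal to the effect direction carry no group signal,
so a re-fitted composite cannot exploit artifacts of the factor model to
reach unrealistic discrimination.  Group differences enter only through
the per-group marginals; within-group latents are standard normal in both
groups.

**Covariates.**  Ages are truncated normal on 18–57 y (35 ± 10 cases,
29 ± 9 controls); sex composition is fixed at the published counts
(23M/17F and 28M/32F); 17 of 40 cases are predominantly inattentive, and
the remainder split 20 combined / 3 hyperactive-impulsive (a typical adult
distribution; the study reports only the inattentive count).  Brown-scale
executive-function ratings are generated as `r·z(composite) + √(1−r²)·ε`
against the activity severity composite with the published target
correlations, so the population correlation equals the target exactly.

**State percentages** are calibrated marginally; they sum to 100 only in
expectation (the published group means themselves sum to 99.4 and 100.8).
Exactly-summing percentages arise only in the epoch-level scoring path.

## Trajectory and task generators

The mechanistic trajectory model alternates heavy-tailed still periods
(Pareto with tail index 1.5, renormalized to fill the session) with
movement bouts: correlated 2-D walks at 50 Hz with Rayleigh step lengths
(about `bout_amplitude_scale` mm of path per second of bout, default
15 mm/s) and a heading random walk whose dispersion is `π·roughness²` —
the quadratic map keeps the upper roughness range from saturating at an
effectively uniform turning distribution, preserving monotone recovery of
roughness by the spatial exponent.  Positions are quantized to the
camera's 0.04 mm resolution.  Frame loss is injected in geometric runs
(mean 10 frames) to mimic occlusion, at the study's mean 18% rate.

The star-task stream presents 240 ms stimuli with a shifted-exponential
ISI (minimum 1 s, mean 2.5 s; "variable ISI" with one free parameter),
90% targets, ≈ 438 trials in a 20-minute session.  The letter CPT has 6
blocks × 3 ISI sub-blocks (1/2/4 s, randomized order within block), 20
trials per sub-block, 10% non-target 'X'.  Responses follow a hidden
five-state process (attentive, distracted, impulsive, random, minimal)
constant within 30-s epochs and Markov across epochs; each state fixes
hit/false-alarm probabilities and an RT distribution, floored at 100 ms
except for the impulsive and random states, which emit anticipatory
sub-100-ms presses.

## Movement measures

* **Microevents** — accumulated path length since the last event crossing
  1 mm (accumulator resets to zero at each event): one isolated 2-mm jump
  is one event; 25.5 mm of steady drift is 25.
* **Immobility duration** — mean length of the runs between consecutive
  microevents (whole session if there are none).
* **Displacement / area** — summed inter-frame path (m) and convex hull of
  visited positions (cm²).
* **Spatial complexity** — divider (compass) dimension: apparent length
  L(r) over a ruler ladder (0.5 mm doublings up to a quarter of the
  bounding-box diagonal), exponent `1 − slope(log L, log r)`, clamped to
  [1, 2].  Validated against an independent grid box-count on a Koch curve
  (analytic dimension 1.262; both estimators within 0.05).  On
  Brownian-like paths the two estimators genuinely diverge at finite
  sampling (box counting has strong logarithmic corrections), so the
  random-walk check asserts only `> 1.3`.
* **Temporal scaling** — box-count exponent of the microevent times over
  widths 0.5–64 s, clamped to [0, 1]; a Cantor-set event pattern recovers
  log 2 / log 3 ≈ 0.63.

**Frame-loss handling.**  Invalid frames are linearly interpolated
(leading/trailing gaps held).  Intensive measures (exponents, area, mean
immobility) use the interpolated geometry; extensive measures
(microevents, displacement) accumulate over truly observed steps only and
are rescaled by the observed-step share, so reconstructed bridges across
occlusions are neither double-counted nor dropped.  On a straight path
both conventions recover the true value to < 1%.

## Attention scoring

Core star-task measures follow the standard definitions (accuracy over all
trials; latency statistics over correct target responses; COV =
100·sd/mean).  Epoch features are (hit rate, FA rate, mean RT, RT sd,
response count) per 30-s epoch, a minimal set that separates the five
described states.  The state classifier is a multiclass Fisher linear
discriminant (pooled within-class covariance) with **uniform priors** —
the classical Fisher rule is prior-free, and empirical priors were found
to bias aggregate percent-time toward the majority state by ≈ 5 points.
Exact score ties resolve by the fixed priority attentive > distracted >
impulsive > random > minimal.  Attention shifts are adjacent-epoch label
changes.

CPT signal detection uses `d' = z(hit) − z(FA)` and
`β = exp[(z²_FA − z²_hit)/2]` with rates clipped to `[1/2N, 1 − 1/2N]`.
Perseverations are responses under 100 ms.  RT/RT-SE slopes are
least-squares against block index (1–6) and ISI level index (1–3); raw
milliseconds are kept even though the printed slope magnitudes suggest the
commercial instrument transforms RT — the summary-level generator samples
these features from the printed rows directly, so no mechanistic
consistency is required.

**Composites.**  The activity severity and distraction severity composites
and the CPT confidence index emulate fixed commercial instruments: they
are fit once on an independent synthetic calibration cohort (default 1000
subjects) — logistic regression on control-standardized feature blocks for
the two severity composites, a two-class linear discriminant on (omission
count, sex, age, β, RT-by-ISI slope) returning posterior × 100 for the
confidence index — and then applied unchanged to the study cohort.  The
**discriminative index** is different by design: as in the original study
it is optimized by (ridge-stabilized) logistic regression on the study
sample itself, which is why its ROC area (≈ 0.96) exceeds what any
out-of-sample combination of the same features could reach (≈ 0.90).
Composite scores are covaried for age and sex before the ROC/DeLong
comparison, matching the published analysis; without this the confidence
index inherits the cohort age difference.

## Inference

ANCOVA is `value ~ group + age + sex` with type-II F; covariate adjustment
is applied only when the covariate's own p < 0.05, and the gate decision
is recorded per measure.  Benjamini–Hochberg q-values are computed within
each measurement family.  Cohen's d uses the pooled-sd convention with a
1,000-resample percentile bootstrap CI (coverage verified ≥ 94% at
d = 0.8).  ROC areas are trapezoidal/Mann-Whitney with midrank ties,
variance and CIs by DeLong's structural components; the paired DeLong test
uses the same components.  AUCs below 0.5 are reported as-is (orientation
is fixed ADHD-high per the hypothesized direction).  `Φ(d/√2)` links the
d and AUC columns as a binormal cross-check.  Note that BH adjustment is
not idempotent (re-applying the step-up rule can only push q-values toward
1); the test suite asserts domination and monotonicity instead.

## Importance and predictive modeling

Variable importance comes from a random forest (default 10,000 trees, 4
variables per split) over all 36 measures: mean decrease in out-of-bag
accuracy under single-feature permutation (per-tree OOB sets reconstructed
from each tree's bootstrap seed) and mean decrease in Gini impurity.  The
predictive harness draws stratified 75/25 splits (default 200; 500 for
random forests) shared across six model families — LDA, an
ordinary-least-squares scorer ("general linear model"), logistic
regression, a single-hidden-layer network (5 units, weight decay 0.1,
lbfgs), an RBF SVM, and a random forest (150 trees inside the harness) —
reporting accuracy, Cohen's κ, ROC-AUC, sensitivity and specificity with
the clinical group positive at the 0.5 posterior threshold.  Paired
activity-vs-attention comparisons use the paired t-test on split-level
metrics, with a Wilcoxon fallback under clear non-normality.

## Problem sizes

Defaults reproduce the study geometry (40/60 cohort, 20-minute sessions,
200/500 CV splits, 10,000 importance trees).  The test suite runs the
qualitative-reproduction checks at reduced sizes chosen as a desk-scale
working set — 10 replicate studies with 25 CV splits per family and 1,500
importance trees — because the orderings under test (composite ROC
hierarchy, shin > head > attention importance, activity-model superiority)
are scale-free and already stable at these sizes.

## What the synthetic cohort does and does not show

Passing tests establish that the *pipeline* reproduces the study's
statistical structure when the data match the printed summaries: effect
sizes, ROC areas and orderings emerge from calibration rather than being
asserted.  The generator does not model practice or fatigue trends within
sessions (block/ISI slope features are sampled, not emergent), comorbidity,
medication effects, zero-inflation beyond what stochastic rounding
induces, or any coupling between a subject's simulated trajectory and
their simulated task responses beyond the shared severity factor.
Absolute composite AUCs on synthetic cohorts run modestly above the
published point estimates (e.g. activity ≈ 0.86–0.89 vs 0.83 [0.75–0.91])
because re-fitted composite weights cannot be worse than the fixed
proprietary coefficients they replace; all ordering conclusions are
unaffected.
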