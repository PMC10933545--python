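# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the open design decisions behind `affectrecall`.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task designs

Both canonical designs are two-alternative probabilistic reward-learning
tasks followed by a preference test of value-based recall.

**Lab design (`study1`).** 14 shapes, 3 learning days.  Each day: a
30-trial baseline block at 0.7/0.3 (the same two shapes on all days), a
single rigged WoF draw (+£15 win / −£11 loss / £0 blank, one outcome per
day, order counterbalanced), then 90-trial blocks at 0.9/0.1 and 0.8/0.2
whose shapes inherit the day's WoF condition.  Two 400-trial preference
tests follow on separate days.  Post-win and post-loss shapes appear on
fixed, counterbalanced screen sides that swap between test days; baseline
and post-neutral shapes are free.  Pupillometry accompanies the first test.

**Online design (`study2`).** 24 shapes, 2 learning days.  Each day: three
40-trial pre-WoF blocks at 0.9/0.1, 0.75/0.25, 0.6/0.4, the WoF draw
(+£14 / −£7), then three post-WoF blocks at the same probabilities.  A
single 456-trial preference test with randomised sides; the
shape-to-probability assignment is randomised per subject.

Within every RL block the two shapes carry complementary probabilities
(p and 1 − p) and exactly one shape is rewarded per trial.  Currency is
stored in integer pence.

**Preference-trial composition.** The experiments report total trial
counts (400 / 456) but not the composition rule.  The generator covers
every presentable unordered pair once, then fills the remaining slots by
resampling equal-probability cross-condition pairs (with probability
`equal_value_priority`, default 1, otherwise uniformly), reflecting the
tests' emphasis on equal-value comparisons.  Under sided presentation,
pairs whose two shapes demand the same exclusive side (win–win, loss–loss)
cannot be shown and are excluded from the grid.  Composition is
seed-deterministic.

## Choice model

Recall of a learned probability p is modelled by the exponential-of-log
weighting function

    w(p) = exp(−δ (−ln p)^γ),   δ, γ > 0,

which preserves the endpoints w(0) = 0, w(1) = 1, reduces to the identity
at δ = γ = 1, and is monotone for all valid parameters.  δ is elevation
(smaller δ lifts the curve), γ curvature (γ > 1 underweights low and
overweights high probabilities); two curves with different γ cross, which
is the signature the win/loss comparison looks for.  Choice is

    P(choose A) = logistic(β · (w_A(p_A) − w_B(p_B))),

with inverse temperature β; the constant 2p reward magnitude is absorbed
into β.  Probabilities are clamped to [1e−6, 1 − 1e−6] inside the
likelihood.

**Arms.** In the sided variant one (δ, γ) pair attaches to each screen
side, and every shape shown on a side is weighted by that side's pair —
this is how affective bleed-over onto co-presented neutral shapes is
expressed.  In the valence variant one pair attaches to post-win and one
to post-loss shapes; baseline and neutral shapes are taken at face value
(identity weighting), since nothing constrains their distortion in a
randomised-side design.

**Fitting.** Bounded L-BFGS-B over (δ₁, γ₁, δ₂, γ₂, β) with
δ, γ ∈ [0.05, 10], β ∈ [0.01, 30], convergence tolerance 1e−10 on the
objective, 20 restarts by default (a Latin-hypercube design over the box
plus one identity start); fits on fewer than 20 trials are refused.
Benchmarks: a zero-parameter random-choice model (P = 0.5 throughout,
per-trial NLL = ln 2 exactly) and an identity-weighting model with a
single fitted β.  Natural logarithms throughout.

**Bias indices.** AuC of a weighting curve is the trapezoidal integral on
a 101-point uniform grid (quadrature error ≪ 1e−3 for these smooth
curves); the bias index is AuC(win arm) − AuC(loss arm), with sided fits
relabelled via the counterbalanced win side first.  The model-free twin
counts choices of high-probability (> 0.5) post-win shapes minus
high-probability post-loss choices; a trial contributes only through the
chosen shape.  The WoF logistic contrast restricts trials to pairs drawn
from two named conditions, codes the outcome as choosing the first-named
condition's shape and the regressor as ±1 by that shape's probability
level; for this single binary regressor the per-subject logistic MLE is
half the log odds ratio of the 2×2 layout, computed in closed form with a
Haldane–Anscombe 0.5 correction (flagged) when a cell is empty.  Group
inference is two-stage throughout: per-subject statistics, then one-sample
or paired t-tests (the degrees of freedom the original analyses report
match the two-stage reading).

**Parameter recovery** simulates subjects across δ ∈ [0.6, 1.6],
γ ∈ [0.5, 1.8], β ∈ [2, 10] — a range bracketing the generator's
population defaults and typical fits of this family — refits each, and
reports Pearson correlations of true versus recovered parameters **on the
log scale**, alongside linear-scale values.  The family is log-linear in
its parameters (ln(−ln w) = ln δ + γ ln(−ln p)) and all three are positive
scale-like quantities; the log scale also keeps the summary robust to the
occasional ridge excursion (a small γ compensated by a large δ near the
box bound) that an otherwise good fit can produce at realistic trial
counts.  The crossover check asks whether a generated win-below /
win-above pattern at p = 0.15 / 0.85 is reproduced by the fitted curves.

## Learning model

A Rescorla–Wagner learner with the delta rule q ← q + α(r − q), q
initialised at 0.5 (the uninformative midpoint), softmax choice with
inverse temperature β.  Feedback in the task reveals the rewarded shape on
every trial, so `full_information=True` is the default and both shapes are
updated toward their realised outcomes; with complementary rewards this
keeps q(A) + q(B) near 1.  MLE fitting uses bounds α ∈ [0.01, 1],
β ∈ [0.05, 30] with 10 Latin-hypercube restarts; a β estimate at a bound
is flagged.  Only this single learner is implemented; asymmetric or
mood-modulated learning-rate variants are out of scope.

## Synthetic-data generator

The generator is the package's study population: every downstream stage is
exercised on cohorts it produces.  A subject is an `AgentParams` draw from
truncated normal population distributions (`DEFAULT_POPULATION`):

| parameter | mean ± SD | role |
|---|---|---|
| α | 0.35 ± 0.15 | learning rate |
| β_learn | 6 ± 2 | learning softmax temperature |
| δ_win, γ_win | 0.9 ± 0.25, 1.3 ± 0.3 | win-arm weighting |
| δ_loss, γ_loss | 1.0 ± 0.25, 0.8 ± 0.3 | loss-arm weighting |
| δ_neutral, γ_neutral | 1.0 ± 0.15 each | neutral/baseline weighting |
| β_pref | 5 ± 2 | preference softmax temperature |
| mood_gain | 0.015 ± 0.005 | normalized-mood shift per £ of WoF outcome |
| pupil_gain | 1.0 ± 0.3 | overall pupil amplitude |

The win arm carries higher curvature and slightly lower elevation than the
loss arm, injecting the crossover of the weighting trajectories and a
positive mean AuC difference of moderate effect size (Cohen's d ≈ 0.6 at
the population level) — strong enough that a 70-subject cohort detects it
reliably, which is the regime the directional tests probe.
`NULL_POPULATION` removes the win/loss asymmetry for type-I-error checks.
Counterbalance arms alternate across subjects; per-subject randomness
derives from a `SeedSequence` spawned off the master seed; ground-truth
parameters are always written alongside the data so recovery never
re-enters the generator.

**Preference choices** are drawn from the weighting model.  For sided
designs the generative arms attach to the screen sides (win-side arm =
win parameters), matching the side-based reading of the analysis model;
for randomised-side designs they attach to each shape's own WoF condition.
This keeps the fitted model well-specified against its generator, which
parameter recovery and the behaviour–pupil coupling require.

**Mood ratings** sit at the design's sampling points on a subject baseline
(0.62 ± 0.08 normalized) with 0.05 rating noise; the WoF outcome shifts
the mean by `mood_gain` × outcome-in-pounds, decaying by 0.8 per
subsequent sampling point within the day.  The lab design stores a 1–9
Likert rating, the online design a 0–100 visual-analogue rating; both are
kept alongside the normalized value.  The linear mood-to-rating
perturbation is an assumption; nothing quantitative constrains it.

**Pupil traces** (per preference trial: 2-s baseline, stimulus onset,
lognormal RT centred near 1.4 s, choice, 4-s outcome window, 0.5-s gap):

* impulse response: gamma-family kernel h(t) = (t/t_max)^n exp(n(1 −
  t/t_max)) with n = 10.1, t_max = 0.93 s (a standard pupillary response
  peaking near 930 ms), normalised to unit peak;
* a pre-choice phasic component with amplitude gain × (0.5 − EV_chosen),
  so lower-value choices dilate more;
* a sustained, kernel-smoothed boxcar over the outcome window whose
  amplitude per (valence, probability-level) cell is 0.25 (+0.10 for
  high-probability choices), with the win cell shifted by
  ±(0.12 + 3.0 × subject's true AuC bias) — upward for high-, downward for
  low-probability choices.  The fixed 0.12 component makes the valence
  crossover a population-level effect; the bias-coupled component ties
  individual pupil indices to individual behaviour;
* AR(1) noise (coefficient 0.97, stationary SD 0.15) and Poisson blinks
  (0.1 s⁻¹, 100–400 ms) marked invalid (samples NaN inside invalid runs).

What the generator does **not** emulate: gaze position and foreshortening,
luminance-driven pupil responses (black-pixel counts are carried as
stimulus attributes and enter the GLM as controls, but do not drive the
synthetic traces), slow session-scale drifts, or any mood-to-weighting
transfer during learning (weighting arms are fixed per subject).  Passing
tests therefore show that the analysis chain recovers the structure this
generator injects — not that real pupil data are this clean.

## Pupillometry pipeline

Order is fixed: linear interpolation across invalid runs (edges held at
the nearest valid value) → zero-phase 3rd-order Butterworth low-pass at
3.75 Hz (order is configurable; the cutoff is the design's) → z-transform
across the session → event-locked epoching with subtraction of the 2-s
pre-event baseline mean.  The interpolated fraction of the choice-locked
0–4 s outcome window drives exclusion: a trial is dropped only when
*strictly more than* 50 % was interpolated.  The pre-choice epoch is
stimulus-locked (0–1.5 s, spanning the typical RT); the outcome epoch is
choice-locked 0–4 s.

The first-level GLM regresses, at each time point, pupil value across
included trials on z-scored trial regressors — model-derived EV of the
chosen shape (from the subject's *fitted* parameters, never the generative
truth), |EV difference| as choice difficulty, and left/right black-pixel
counts — plus an intercept.  Second level: one-sample t across subjects at
each time point, reporting uncorrected p < 0.05 runs longer than 100 ms
and the |t| peak (no cluster correction; the original analyses report a
peak window without stating one).  The outcome window is averaged in four
1-s bins; a 3 (valence) × 4 (bin) repeated-measures ANOVA (Greenhouse–
Geisser corrected, via pingouin) is run separately for low- and
high-probability chosen shapes.  The sustained-dilation index integrates
(trapezoid over bin centres) the win − mean(loss, neutral) contrast for
high-probability choices minus the same integral for low-probability
choices; its exact form is a documented stand-in, as the original
definition is not printed.  Binocular combination is out of scope: the
generator emits one trace, and `PupilSession` accepts any single series.

## Group statistics and pipeline

Paired and one-sample t-tests, Pearson correlations and OLS go through
scipy/statsmodels behind thin helpers so toy-size oracles can pin them.
The covariate model is delta-AuC ~ intercept + z(BDI) + age + gender +
WoF-order with the non-BDI covariates mean-centred, so the intercept
estimates the covariate-adjusted mean bias and its t-test is the
positive-bias confirmation.  Post hoc tests after rmANOVA use Bonferroni
correction; pointwise pupil tests are reported uncorrected with the
run-length rule.  `run_pipeline` writes every table with the config hash,
plus a manifest (config, seeds, per-stage row counts), so outputs from
different configurations are detectable.

## Problem sizes and numerical choices

The heavy validation runs are scaled to single-CPU budgets as the
package's own choice of problem size; thresholds are never adjusted to
the scale:

* parameter recovery: 50 synthetic subjects × 456 trials, 8 restarts;
* directional replication: 20 cohort replicates per check (success
  required in ≥ 90 %, i.e. ≥ 18/20) — behavioural cohorts of 70 subjects
  at the canonical 456 trials; pupil cohorts of 39 subjects with 120
  preference trials and 100 Hz traces (the canonical 500 Hz × 400-trial
  session is ~17× larger and changes nothing but constants);
* type-I checks: 200 replicates of closed-form contrasts.

Degenerate inputs fail loudly: all-invalid pupil sessions, zero-variance
z-scores, epochs outside the recording, rank-deficient GLM designs
(collinear columns are named), sub-20-trial fits, missing ANOVA cells
(subject dropped and logged on the returned table).  Likelihoods floor
per-trial probabilities at 1e−12.

## Known limitations

* The exclusion bookkeeping for real cohorts (inverted-strategy subjects,
  insufficient unique mood ratings, pupil dropout) is expressed through
  the per-stage errors and inclusion flags rather than a dedicated
  exclusion report.
* Hierarchical/Bayesian estimation is out of scope; all fits are
  per-subject MLE, matching the two-stage inference used throughout.
* The sided variant estimates side-attached weighting, so condition-pure
  effects in sided data are recovered only up to the side mixture —
  a property of the design, not the implementation.
* Magnitude-sensitive utility curvature is not modelled (reward magnitude
  is constant at 2p).
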