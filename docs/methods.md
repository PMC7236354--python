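# Methods

## The task and its scoring model

The engine models a 5-minute rapid visual categorization test with backward
masking. Each trial presents one grayscale image (animal vs. non-animal) for
100 ms, a 20 ms blank inter-stimulus interval, then a 250 ms dynamic mask —
8 frames of 31.25 ms each drawn from a 16-frame pool. The pool is built from
a single uniform white-noise image, low-pass filtered with Gaussian kernels
at four octave-spaced widths (σ = 8, 4, 2, 1 px on a 256 px canvas, scaled
with the canvas), each thresholded at its own median into a {0, 255}
pattern, and expanded into four variants (rot90, rot180, horizontal and
vertical mirror; the unrotated original is not kept, which is the only
composition that yields exactly four frames per scale). Mask sequences draw
two distinct frames per scale without replacement and shuffle the eight.
The filter family and the median threshold are our choices where the
construction was otherwise underdetermined; both are standard for
coarse-to-fine binary noise masks, and the median guarantees the ~50/50
pixel coverage that the binary-coverage test asserts.

Sessions start with a 10-image practice block. Strictly more than 50%
correct admits the participant; at or below chance the instructions repeat
with a second, disjoint 10-image block; a second failure aborts. Exactly
half correct fails (chance level). Practice trials are phase-tagged and
never reach the scorer.

Scoring: reaction times of all responded main trials pass through Tukey
boxplot fences, q1 − w·IQR and q3 + w·IQR with w = 1.5, quartiles by linear
interpolation between order statistics, *strict* inequality at the fences
(so a degenerate IQR removes only values unequal to the quartile). Trials
removed as RT outliers leave both the accuracy denominator and the speed
computation; non-responses carry no RT, count as incorrect, and stay in the
denominator. Whether fence removal should also reduce the accuracy
denominator is not fully determined by the scoring description; we remove
at the trial level because the validity rule counts "observed images",
i.e. trials. A result is invalid when the removed fraction of observed main
trials exceeds 40% (exactly 40% remains valid). Note the fences have a
~25% one-sided breakdown point: the >40% invalidity state is reachable only
with extremes on both sides of a tight central mass, not by one-sided
contamination, which the quartiles then absorb.

Accuracy is percent correct; speed maps the mean correct-response RT
through `min(100, 100·exp(−meanRT/1025 + 0.341))`, which saturates at 100
for meanRT ≤ 1025 × 0.341 = 349.525 ms; the summary score is their product
rescaled to 0–100. With no correct responses the speed term is undefined
and reported as 0 (the summary score is then 0 through the accuracy factor
anyway). Performance trends are ordinary-least-squares slopes: per-trial
correctness (0/1) against trial index, and the per-trial speed transform of
correct RTs against trial index; a `trend_window` (default 10) sets the
minimum number of trials.

## The classifier

Features, in fixed order: summary score, accuracy trend, speed trend, age
(years), gender (0/1 indicator), education (years). The model is a softmax
(multinomial) logistic regression retained in its multi-class form so more
than two cognitive statuses remain expressible; with two classes it reduces
to binary logistic regression with the reference class pinned at logit 0.
Features are z-scored with training-set statistics (population SD, which
makes standardization invariant under dataset duplication); the fit
minimizes the negative log-likelihood plus an L2 penalty λ/2·‖w‖² on the
non-intercept weights (λ default 1.0, L-BFGS, gradient tolerance 1e-8) — a
strictly convex problem, hence deterministic. λ = 1 stabilizes the many
small-n refits of leave-one-out evaluation. Constant features are rejected
by name. In leave-one-out cross-validation the scaler and the weights are
re-estimated per fold, so the held-out subject cannot leak into
standardization (asserted by a test that injects an absurd held-out value).
The ROC is a threshold sweep over the unique held-out probabilities, the
area is the trapezoid integral (equal to the pairwise concordance statistic
with ties counted half — asserted against that oracle), and the reported
operating point maximizes Youden's J; the published operating point's
selection rule was not stated, so J is our choice and the full curve is
returned alongside.

## Psychometrics

Impairment labelling against a user-supplied norms table: impaired iff any
subtest z ≤ −2 (severe) or at least two subtests z ≤ −1 (mild); boundaries
inclusive, the conservative reading toward detection. The norms themselves
are configuration — fixtures default to the control group's summary
statistics. Cohen's d uses the simple-average pooled SD
√((s₁² + s₂²)/2) with n−1 SDs; this variant reproduces the published
worked-example values for four of the six score rows to two decimals (the
remaining two rows match no standard variant and are excluded from
assertions). Pearson correlations take two-sided p from the t transform.
Test-retest reliability is Pearson r between administrations, banded
"adequate" strictly above 0.70 and "good" strictly above 0.80. Paired
comparisons use the paired t-test with d = mean difference / SD of
differences; a zero-variance difference reports d = 0, t = 0, p = 1 rather
than dividing by zero.

## The synthetic cohort generator

No participant data are distributable, so the generator defines the study
conditions under which everything is tested.

Per trial: P(correct) = (1 − lapse)·σ(ability − 4·(difficulty − ½)) +
lapse/2, with difficulty ∈ [0, 1] from the stimulus set and the slope 4
chosen so the difficulty range spans roughly ±2 logits; RT = shift +
exp(μ + 0.3·difficulty + ε), ε ~ N(0, σ²) — a shifted lognormal with a
0.3 log-ms difficulty penalty so harder images are slower; with probability
`outlier_prob` (default 0.02) the RT is replaced by a uniform draw from
[3000, 10000] ms, emulating distracted trials. Defaults: shift 200 ms,
σ = 0.25, lapse 0.02.

Per subject: a standard-normal latent cognitive factor loads (0.9) on both
ability and −log-RT location, with independent residuals, and loads (0.8)
on the three battery subtest scores, which are otherwise drawn from the
published group means/SDs. These loadings were set so the simulated
combined-group correlation between the summary score and the
processing-speed subtest lands near the published convergent validity
(r ≈ 0.82 combined; the simulation gives ≈ 0.81); the latent factor is
also what makes norm-based impairment labels learnable from test features.
Demographics follow the published group tables (patients: age 37.24 ± 10.2,
education 14.21 ± 3.16, 82% female, EDSS 1.27 ± 1.8, disease duration
6.8 y; controls: 36 ± 10, 14.81 ± 2.5, 70% female), truncated to the study
ranges. Serum NfL is generated for patients only as
110 − 1.0·score + N(0, 10.3²); the noise SD puts the population
score–biomarker correlation near −0.79, the published association.

Group ability/RT distributions are calibrated by iterated moment matching
(`calibrate_group_params`): each round simulates 400 subjects through the
full session/scoring pipeline with common random numbers, nudges mean
ability toward the accuracy implied by the target score (power-law split
`acc = 100·(target/100)^0.35`), applies a Newton-style correction to the
log-RT location through the inverse of the speed transform, and rescales
both spreads by the SD ratio; tolerance ±1.0 on the mean, ±1.5 on the SD.
The shipped defaults are the calibrated solutions for the published group
targets (patients 63.67 ± 13.30, controls 78.43 ± 9.86). Unattainable
targets (e.g. zero SD — trial-level noise floors the score SD) raise an
error carrying the best achieved moments.

What the generator does *not* emulate: real photographic image statistics
(stimuli are procedural blob/polygon silhouettes; the difficulty scalar is
assigned, not estimated), sequential effects (fatigue, drift — per-trial
probabilities are exchangeable, so simulated trend features are
approximately zero and carry little class information; classification on
simulated cohorts is driven mainly by the summary score and demographics),
response deadlines or non-responses (every simulated trial is answered),
and any longitudinal change mechanism (a retest is just a fresh session
from the same subject parameters, so practice effects are absent by
construction — consistent with the no-learning-bias property of the test
being modelled, but assumed rather than demonstrated). Passing tests
therefore show the pipeline's internal correctness and its behaviour under
these calibrated conditions, not performance on clinical data.

## Problem sizes and numerical choices

Simulated studies use the published group sizes (91 patients, 83 controls);
acceptance checks average the leave-one-out AUC over 10 cohort seeds and
the between-group effect size over 20, sizes at which those Monte-Carlo
means are stable to well within the asserted tolerances. Severely impaired
simulated subjects occasionally fail the practice gate twice (a few per
cohort); their sessions abort, they carry no score, and analyses drop them
— mirroring how an aborted administration yields no result. Quartiles use
linear interpolation (numpy's default) so the fences are reproducible;
mask-pool validation is cached on the pool object since frames are
immutable by convention; all stochastic APIs take either an integer seed or
a numpy Generator, and cohort simulation is bit-exact for a fixed config.
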