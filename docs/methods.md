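# Methods

`vdgradient` implements the analysis chain used to ask whether four
simultaneously characterized brain areas, ordered 1–4 along a hypothesized
anatomical axis, form a *functional gradient* in a two-offer risky-choice
task: does decodability of task variables and the intrinsic timescale of
spontaneous activity increase along the order, while simpler firing
properties (baseline rate, Fano factor, dimensionality) do not?

## Task and data model

Each trial presents two offers asynchronously.  An offer is a reward
magnitude *m* (µL of juice) delivered with probability *p*; its expected
value is EV = *m·p*.  Offer 1 appears at *t* = 0 for 400 ms, followed by a
600-ms blank; offer 2 follows the same schedule; the choice fixation is
acquired 100 ms later (so offer-2 onset is 1.0 s and the choice anchor
2.1 s).  Spike times are stored per (neuron, trial) in seconds relative to
offer-1 onset and must span at least [−2 s, end of the post-choice epoch]:
the 2-s task-free pre-offer window feeds the baseline and timescale
analyses.

Analysis windows are half-open and built from 20-ms bins.  The four
analysis epochs are 500-ms windows at zero offset from offer 1, offer 2,
the choice fixation, and choice resolution (the end of the choice epoch).
The exact choice anchor is not fixed by the task description; we anchor to
the choice fixation.  Epoch firing rates are spike counts divided by the
epoch duration; where analyses require comparability across neurons the
rates are z-scored per neuron across trials, and zero-variance neurons are
kept at z = 0 with a flag so population matrices keep a stable shape.

## Synthetic data generator

No public recordings exist for this task, so the generator is a
first-class module that emulates the statistical structure every stage
assumes.  It is a ladder of assumptions, not a biophysical model:

* **Behavior.** Choice is Bernoulli with P(choose offer 1) =
  σ(β·(EV1−EV2) + side bias).  The default β = 0.0264 logit/µL was frozen
  by bisection so the simulated higher-EV choice rate is ≈80% at 10,000
  trials, the midpoint of the per-area session range the task produces.
  Offer types are small/medium/large (125/165/240 µL) with mix
  (12.5%, 43.75%, 43.75%).  All offer probabilities are drawn uniformly on
  [0, 1] by default; this keeps offer probability and magnitude independent
  across trials.  (A variant where the small offer is a sure thing is
  available as `TaskParams(safe_prob_one=True)`; note that it induces a
  −0.31 trial-wise correlation between probability and magnitude, which
  propagates into a structural +0.31 correlation between their regression
  weights under the null — the weight-correlation signatures should then be
  read against that baseline, not against zero.)
* **Spiking.** Each neuron is a doubly-stochastic Poisson process:
  rate(t) = baseline + OU(t) + epoch-locked linear drive, clipped at zero,
  discretized at 10 ms (spike times jittered uniformly within a step).
  The Ornstein–Uhlenbeck latent rate has exponential autocovariance with
  time constant `ou_tau` and stationary SD `ou_sigma`; the timescale stage
  fits exactly this exponential, which makes τ recovery a well-posed test.
  Baselines are log-normal with mean 5 sp/s, and `ou_sigma` defaults to
  baseline/3 so zero-clipping is rare (the residual clipping bias is
  small and shared across areas).
* **Tuning.** Per-neuron weights (sp/s per z-unit of the regressor) act
  only inside their epoch: probability, magnitude, EV1 and offer side in
  epoch 1; EV1 and EV2 in epoch 2; chosen offer, chosen side,
  chosen/unchosen value and previous-trial choice/reward in the choice
  epoch; chosen side again post-choice.  The seven core weights are drawn
  from a multivariate normal realizing the target population correlations
  (probability↔magnitude +0.5; EV1-epoch1↔EV2-epoch2 +0.5;
  EV1-epoch2↔EV2-epoch2 −0.5) — the ground truth for the integration,
  alignment and inhibition signatures.  The remaining choice-epoch weights
  are independent draws so every decoder in the battery has signal.
* **The gradient preset.** Four areas with the recorded neuron counts
  (156, 146, 213, 129), OU timescales (110, 150, 320, 450) ms, and a
  per-neuron SNR ladder (0.5, 0.75, 1.0, 1.6) multiplying all tuning
  weights.  The SNR ladder was calibrated once so that the *population*
  decodability increases strictly with order: neuron counts are not
  monotone in order (the order-3 area has the most neurons, which alone
  boosts its decoding accuracy), so per-neuron SNR must more than
  compensate for the order-4 area's smaller sample.  The preset reproduces
  qualitative orderings only; printed per-area accuracies are not targets.

What the generator does *not* emulate: refractoriness, bursting, cell-type
heterogeneity, cross-neuron noise correlations (irrelevant after
pseudo-population resampling, which destroys them anyway), eye movements,
session-to-session drift, and the token-economy details of one task
variant (reward is reduced to a `rewarded` flag).  Passing tests therefore
show the *estimators* are correct and calibrated, not that real cortex
behaves like the generator.

Seeding: one master seed spawns named substreams (trials, weights, spikes,
each decoder) via `SeedSequence`, so trial generation, weight draws and
spike draws are mutually isolated and each stage is reproducible alone.

## Per-neuron selectivity and latency

Value tuning is the Pearson correlation between a neuron's epoch rates and
the offer EV, two-sided test at α = 0.05 (the conventional per-neuron
criterion; no multiple-comparison correction at the neuron level).
Whether a significant *proportion* of neurons is tuned is a one-sided
exact binomial tail P(X ≥ k | n, 0.05).  Time-resolved selectivity slides
a 500-ms window in 20-ms steps (window width matching the epoch width;
output aligned to window centers).

Response latency is computed under five definitions — peak rate, first
significant value correlation, significant-to-peak, peak |rate − mean|,
and first excursion beyond mean ± 2 SD (two-sided, to catch suppressed
neurons).  Latency resolution is the 20-ms bin, reported at bin centers,
ties to the earliest bin; neurons with no qualifying bin are missing and
excluded from means, as are negative significant-to-peak intervals.
Area × offer differences are tested with a two-way ANOVA (type II) on
neuron-level latencies, missing values dropped listwise; empty cells and
zero-variance data raise errors rather than returning nonsense.

## Choice-process signatures

Per neuron, z-scored epoch rates are regressed (OLS) on standardized task
variables; regressors are standardized so weights are comparable across
neurons, and near-collinear designs (|r| > 0.999) are rejected naming the
offending pair.  Coefficient vectors are then correlated across the
population: integration (epoch-1 weights for probability vs magnitude,
expected positive), alignment (epoch-1 EV1 weight vs epoch-2 EV2 weight,
expected positive), inhibition (epoch-2 EV1 vs EV2 weights, expected
negative).  The same correlations on absolute weights index overlap of the
functional populations and are invariant to sign flips of any neuron's
weights.  We report the Pearson r with a two-sided p, a Fisher-z 95% CI on
r, and the regression-slope CI (the ribbon usually drawn on such scatter
plots).  Neurons with failed fits are excluded pairwise with counts
reported.

## Intrinsic timescales

Spike counts in 20-ms bins over the 2-s pre-offer window are correlated
across trials between every bin pair; the autocorrelation at lag kΔ
averages all pairs with |i−j| = k, for lags 20–720 ms.  Bin pairs with
zero across-trial variance are skipped (their correlation is undefined),
silent neurons are excluded and counted.  Per-neuron curves are averaged
into an area curve (SE across neurons) and fitted with

    R(kΔ) = A·[exp(−kΔ/τ) + B]

by bounded least squares (τ ∈ [1, 5000] ms, A ∈ [0, 2], B ∈ [−1, 1]),
multi-started from τ₀ ∈ {50, 100, 300, 600} ms with the best SSE kept; all
lags enter the fit (no first-lag exclusion).  A fit is flagged
non-converged when the optimizer fails, sits on a bound, or the curve is
flat (τ unidentifiable); values are still reported.  The cross-area
gradient statistic is the Pearson correlation of the four τs with the
order 1–4.  On OU ground truth (110/150/320/450 ms, 150 neurons × 500
trials) recovery is within ±10% with rank order preserved; the acceptance
suite enforces ±20%.

The task's nominal inter-trial interval is shorter than the 2-s analysis
window; the estimator simply consumes whatever ≥2-s pre-offer span the
data provide, and the generator emits one (baseline + OU only).

## Pseudo-population decoding

For each of 12 label/epoch pairs (EV1 in epochs 1 and 2; EV2 and
EV1−EV2 in epoch 2; offer-1 side in epoch 1; chosen offer, chosen side,
chosen/unchosen value, previous choice and previous reward in the choice
epoch; chosen side post-choice), continuous labels are binarized by a mean
split (ties to the low class) and each neuron's trials of each class are
resampled with replacement into an n × 1000 matrix per class (draws
independent across neurons).  Each of 1000 repeats (200 in the scaled-down
acceptance run) splits both classes in half, z-scores features with
training-half statistics, trains a linear SVM (C = 1) and scores the
held-out half; the error bar is the SE over repeats.

The shuffle null permutes the class assignment of the pooled pseudo-trials
before the identical split/train/test — this is the only permutation
scheme whose expected accuracy is exactly 50%.  Permuting *trial* labels
instead leaves the random trial→class partition shared between train and
test halves; because pseudo-trials are resampled with replacement from a
few hundred trials, a classifier learns that partition and "chance"
inflates to ~66% at 150 neurons.  For the same reason the real-label
accuracies contain a population-size–dependent optimism shared with any
resampling-based pseudo-population decoder; the decimation control
(subsampling every area to 125 neurons, seeded, without replacement)
equalizes it, and the multinomial EV control (six consecutive equal-count
EV bins, multinomial logistic regression, linear multiclass SVM optional)
checks that binarization did not hide graded value coding.

Cross-area gradient tests are Spearman correlations against the order
1–4, either on the four area means (scalar mode) or pooling all repeats
with their order labels (distribution mode, as used per label).

## Intrinsic-property controls and behavior

Baseline rate is the mean firing rate in a pre-offer window, default
[−2, −1] s (the task description of the baseline window is internally
inconsistent; we default to the second that does not overlap the final
second of the timescale window and leave it configurable).  The Fano
factor is the across-trial variance/mean of 100-ms counts per (neuron,
bin), zero-mean bins skipped, averaged across neurons per bin and then
summarized; it is 1 for a homogeneous Poisson process and rises with
latent-rate variance.  Dimensionality is the explained-variance spectrum
of the time × neurons matrix of per-neuron z-scored trial-averaged 20-ms
time courses, with successive slopes taken as simple differences between
adjacent PCs' fractions.  Behavior is summarized per session as the
proportion of unequal-EV trials on which the higher-EV offer was chosen,
tested with a one-sample t-test (null 0 as conventionally reported for
this task; configurable, 0.5 being the natural chance-level alternative),
plus a pooled logistic fit of P(choose offer 1) against EV1−EV2.

## Problem sizes and numerical choices

Default pipeline runs use 500 trials/area and the preset neuron counts;
the acceptance suite uses 200 decoder repeats, 150-neuron recovery areas
and a 1000-neuron null population — sizes at which every calibrated
quantity has comfortable margin (binomial SE of the type-I fraction at
1000 neurons is 0.7 points; τ recovery error ≤10% against a ±20% bound).
Bin arithmetic uses a 1e−12 relative fuzz so float error at exact bin
edges cannot reclassify spikes, while genuinely out-of-window times stay
excluded.  Degenerate inputs (flat ACFs, constant latencies, single-level
labels, all-tied rank inputs) raise typed errors or are flagged, never
silently imputed.

## Known limitations

* Pseudo-population accuracies are method-relative: they carry the
  resampling optimism described above and should only be compared within
  the same trial counts and (after decimation) neuron counts.
* One exponential fit per area; per-neuron τ distributions are out of
  scope, and strongly heterogeneous τ within an area would bias the area
  fit toward a mixture.
* The generator's epoch drives are piecewise-constant; latency analyses on
  synthetic data therefore exercise the estimators' conventions (bin
  centers, tie-breaks) rather than realistic response dynamics.
* The binomial population test treats neurons as independent; within-session
  dependencies in real data would make it anti-conservative.
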