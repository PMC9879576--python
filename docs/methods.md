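# Methods

## Problem and pipeline

`pentail` implements a two-stage approach to detecting tail-biting
behaviour in group-housed pigs from overhead video of whole pens, without
animal tracking. The first stage turns each 10-fps frame into a latent
feature vector with a pretrained convolutional backbone (the reference
backbone is VGG-16 truncated after its first fully-connected layer,
yielding 4,096 features per 224×224 frame). The second stage classifies
short windows of consecutive frames as containing / not containing a
biting event, using either

* an **LSTM** over the window's feature sequence (CNN-LSTM), or
* a **CNN** over the window rendered as an N_Obs × N_PC "sequence-image"
  (CNN-CNN).

Between the stages, features are cleaned and compressed: columns with
exactly zero sample variance across the whole dataset are dropped;
optionally the first N_PC principal components are retained (PCA fitted
on all pens simultaneously); each output dimension is min-max scaled to
[0, 1].

### Evaluation

A window is predicted positive when the model's biting probability is
*strictly above* a threshold t. The threshold is swept over
0.00–1.00 in steps of 0.01; at each point sensitivity TP/(TP+FN),
specificity TN/(TN+FP), FPR = 1 − specificity and the major-mean accuracy
MMA = (sensitivity + specificity)/2 (balanced accuracy) are recorded.
**nMMA** is the MMA at the conventional t = 0.50; **btMMA** is the grid
maximum, with ties broken toward the smallest (most sensitive)
threshold. Under the strict-> convention a probability of exactly 0.5 is
a negative prediction at t = 0.50, and perfectly separated 0/1 scores
are already separated at t = 0.00. ROC/AUC is computed by trapezoidal
integration over the same 101 grid points (appending (0,0)/(1,1) when
the grid does not reach them), not over unique score cutpoints; with
grid-aligned scores this agrees with the Mann–Whitney rank AUC to well
under 0.01. Degenerate test sets (a class absent) yield flagged missing
rates rather than silent 0 or 1. Per-behaviour-category breakdowns
report sensitivity for tail-biting windows and specificity (share
predicted no-biting) for each distractor category.

### Cross-validation and the final model

Pens are the experimental unit. Two pens form the outer test set and are
untouched by every fitting step. The remaining eight learning pens form
four folds: each fold tests on a disjoint pen pair, early-stops on one
randomly drawn validation pen and trains on the other five. Training
sets are balanced 1:1 by randomly undersampling negative windows
(positives are always kept); validation and test sets are never
balanced. Training uses Adam (learning rate 0.001), batch size 16,
categorical cross-entropy, and stops when validation loss has not
improved for 10 consecutive epochs, restoring the best-epoch weights.
The final model trains on all learning pens (minus one validation pen)
and is evaluated per outer pen and combined.

The default protocol fits PCA and min-max scaling on *all* pens
including test pens, reproducing the original study's procedure and its
mild information leakage; `fit_on_train` restricts fitting to training
pens. Whether the original scaling was fitted per-split is not
documented; both modes are provided and the faithful mode is default.

### Architecture grammars

Both families are generated from a small grammar (the cross-validation
grid):

| parameter | values |
|---|---|
| N_Obs (frames per window) | 10, 20, 30 |
| N_PC | 4, 8, 16, 32, 64, 128, 256, 512, or no PCA (all retained features) |
| layers | 1, 2, 3 |
| LSTM node rule | mean = round((D+2)/2), half-mean = round((D+2)/4), sum = D+2 |
| CNN first-layer filters | 8, 16, 32, 64 (doubling per layer: F, 2F, 4F) |
| dropout | 0, 0.1, 0.2 |

D is the model's input width (N_PC, or the retained-feature count for
the no-PCA baseline; 3,485 on the reference data), and 2 is the number
of output classes. Every LSTM/conv layer is followed by batch
normalization; dropout sits after the last block; a 2-unit softmax head
closes the network. Choices the source protocol leaves open, decided
here:

* **Node rounding** uses round-half-to-even (Python `round`); the grid's
  values make ties rare, e.g. half-mean at D = 4 gives round(1.5) = 2.
* **Multi-layer LSTM node allocation**: the rule's total is divided
  equally over the layers (ceil per layer, minimum 1).
* **Convolutions** are 3×3, stride 1, *same* padding, no pooling — same
  padding keeps every (N_Obs, layers) grid point buildable.
* **Sequence-images** are the scaled N_Obs × N_PC matrix used verbatim
  as a 1-channel input: no resizing or quantization (an optional 16-bit
  PNG export exists for inspection, with round-trip error ≤ 2⁻¹⁵).
* **Windows are non-overlapping** ("divided into" sub-sequences); a
  trailing remainder shorter than N_Obs is discarded, windows never span
  pens, and an event crossing a window boundary yields two positive
  windows. Obstructed (excluded) frames are dropped before windowing,
  closing the gap in the retained order.
* **Window categories** follow the priority tail_biting >
  negative_social > nursing > no_event over member frames.
* The reference CNN grid used one fewer N_PC level than the LSTM grid
  (its ANOVA has 7 vs 8 degrees of freedom for N_PC); which level was
  omitted is undocumented. The default CNN grid omits 512 and keeps the
  no-PCA baseline (needed for baseline contrasts); this is configurable.

### The numpy network engine

No deep-learning framework is a dependency: the networks here are small
(tens of units, thousands of windows), so `pentail.nn` implements the
exact layer vocabulary the grammars need — LSTM (gate order i, f, g, o,
unit forget bias, Glorot kernels, orthogonal recurrent init), 3×3 same
convolution, batch normalization (channel-wise over all other axes,
eps 1e-3, momentum 0.99 running statistics), inverted dropout, dense
softmax head — with manual backpropagation and Adam (β₁ 0.9, β₂ 0.999,
eps 1e-7). All gradients are verified against central finite differences
in the test suite; trainable-parameter counts follow the closed forms
4u(d+u+1) per LSTM layer, 9·c_in·c_out + c_out per convolution, 2
per-channel scale/shift for batch norm, and (d+1)·2 for the head.
Everything is seeded through `numpy.random.Generator`; with fixed seeds
a full train/evaluate run is bit-reproducible on CPU. Intermediate LSTM
layers emit full sequences and their batch normalization is applied per
time step.

### Hyperparameter statistics

Cross-validation emits one metric value (nMMA, btMMA) per grid point ×
fold × inner-test pen. Effects are estimated with a linear mixed model:
metric ~ categorical fixed effects (N_Obs, N_PC, layers, node rule /
filters, dropout) + a random intercept per test pen, fitted by REML
(`statsmodels` MixedLM; non-converged REML falls back to ML with a
flag). Factor tests are Wald F-tests on the fixed-effect contrasts,
which coincide with Type-III tests on the balanced grids the CV
produces; the ANOVA table's sum-of-squares column is reported on the
residual-variance scale (SS = F·df·σ̂²). Post-hoc pairwise contrasts use
estimated marginal means (equal to coefficient differences under
treatment coding with main effects only) with Tukey studentized-range
adjustment; for N_PC the contrasts against the no-PCA level double as
the baseline comparisons. Factors are treated as categorical, the
response is untransformed, and the per-test-pen (not per-fold) response
is used — required for the pen random effect to be estimable.

## Synthetic data: what it emulates and what it does not

The farm videos behind the reference results are not public, so the
generator (`pentail.synthetic`) produces per-pen streams with the
statistical structure the pipeline assumes:

* **Background features**: stationary AR(1) Gaussian noise per feature
  dimension (unit marginal variance, autocorrelation `noise_ar1`,
  default 0.5) — the cheapest temporal structure under which window
  length matters.
* **Events**: per pen, a Poisson number of tail-biting events
  (`event_rate`, default 6) with durations from a mixture putting 55% of
  mass uniformly on 1–4 s and the rest on a truncated-exponential tail
  over (4, 45] s (scale 8 s), matching the reported duration range and
  short-event share. Segments are placed uniformly without overlap.
* **Signal**: during biting frames a fixed random `signature_dim`-sparse
  unit direction (default k = 16) is added with magnitude `effect_size`
  (default δ = 5). Distractor behaviours (negative social, default 6
  events/pen; nursing, default 4) add their own directions at δ/2,
  deliberately at a 60° angle to the biting signature so specificity is
  non-trivial.
* **Obstructions**: a small fraction of event-free frames (0.5%) is
  flagged excluded, exercising the gap-closing logic without disturbing
  event accounting.

Default pens are 3,000 frames (5 min at 10 fps) — shorter than the
hour-long farm recordings — with event density raised correspondingly so
each pen still carries a handful of events; positive-class share is
configurable down to the ≤2% regime of the real data. What the
generator does **not** emulate: photorealistic appearance, camera
artifacts, label noise, non-stationary activity rhythms, and feature
distributions of a real convolutional backbone (real VGG-16 features are
non-Gaussian and highly correlated). Passing the end-to-end tests
therefore demonstrates that the pipeline's machinery is correct and can
recover a planted, linearly separable temporal signature — not that the
reported farm-data accuracies transfer.

A toy image renderer (`render_toy_frames`) writes grayscale frames with
a bright motif in one grid cell on biting frames, to smoke-test the
image→feature extraction path with the grid-pooling stub extractor. The
extractor is a pluggable contract; pretrained weights are never required
to build or test the package.

## Problem sizes used by tests and the acceptance script

Unit tests run on 6 pens × 1,200 frames × 96 features. The end-to-end
recovery runs use the generator defaults — 10 pens × 3,000 frames ×
4,096 features, δ = 5 (and δ = 0 for the null control), LSTM/CNN with
N_Obs = 10 and N_PC = 16, ≤ 50 epochs — and evaluate on the two held-out
pens. The mixed-model recovery simulation uses the full LSTM factor grid
(486 points × 8 pens) with a +0.1 planted N_PC effect (levels ≥ 32), pen
intercept SD 0.01 and residual SD 0.02, 20 replicates. Grammar parameter
counts are verified closed-form against independently written formulas
over the complete grid, and against actually built networks for every
count-distinct grammar up to width 512 plus no-PCA spot checks (the
largest no-PCA LSTMs, ~10⁸ parameters, are checked by closed form only —
building them costs tens of seconds in orthogonal initialization alone).

## Known limitations

* The published per-pen non-biting image counts and unique-event counts
  do not sum to their printed totals (322,006 vs 327,336; 233 vs 208);
  `summarize` always reports recomputed sums. The biting-image column is
  consistent (5,330). One printed aggregate specificity (92.10%)
  disagrees with its own printed counts (5624/6108 = 92.08%).
* Unique events are defined as maximal runs of consecutive biting frames
  within a pen — the only definition computable from frame labels.
* Frame-rate downsampling uses nearest-index rounding from the source
  rate (59.94 fps → 10 fps); only the target rate is specified upstream.
* `run_grid` at the full faithful grid × folds is thousands of
  trainings; the default configurations run reduced grids, and the grid
  runner is restartable (per-point hash-derived seeds, incremental CSV).
* MixedLM Wald F-tests use a residual-style denominator df
  (n − k_fixed), not Satterthwaite/Kenward-Roger approximations; on the
  large balanced CV tables this distinction is negligible.
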