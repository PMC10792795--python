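# Methods

## Problem and pipeline

Radiographic periodontal bone loss (PBL) on a molar is defined by three
anatomical landmarks per side (mesial and distal): the cementoenamel junction
(CEJ), the most coronal point of the alveolar crest, and the root apex.  With
root length `A = ‖apex − CEJ‖` and bone height `B = ‖apex − crest‖` (pixel
Euclidean distances), the loss percentage is

    PBL% = (A − B) / A × 100,

staged per the Classification of Periodontal and Peri-Implant Diseases and
Conditions: stage 1 below 15%, stage 2 from 15% to 33% inclusive, stage 3/4
above 33%.  The pipeline estimates the six landmarks on a cropped molar image
in three steps: a statistical prior proposes keypoints, a convolutional
network refines them against the image, and the geometric rule above converts
the refined keypoints into per-side percentages and stages.

## Crop preparation

Crops are cut from bounding boxes; keypoints are stored normalized by crop
width/height (origin top-left, x rightward, y downward).  A side is usable
only when all three of its landmarks are labeled; partially labeled sides are
cleared rather than guessed.  Upper-jaw crops are rotated 180° so every crop
presents the apex at the bottom — this standardization helps the refiner
converge because the geometry no longer bimodal.  Jaw membership is an
annotation field: the package does not infer it from pixels.

Splits reserve a fixed-size unlabeled test set drawn uniformly at random,
then divide the remainder `floor(0.8·n)` / rest into training and validation.
With 2010 crops and a 40-image test set this yields 1576/394/40.

## Component 1 — statistical keypoint prior

Each of the 12 coordinates is modeled independently by a one-dimensional
distribution.  Candidate families are normal, log-normal, beta, gamma,
uniform and logistic; within a family parameters are estimated by maximum
likelihood (`scipy.stats.<family>.fit`), and families are ranked by the sum
of squared differences between the empirical histogram density (100
equal-width bins over the observed range) and the fitted density.  The
minimizer per slot is stored; zero-variance slots become a point mass.
Samples are clamped to [0, 1] rather than rejected, since rejection can loop
indefinitely on badly fitted tails.  No dependence between coordinates is
modeled.

Two caveats a user should know:

* The histogram-SSE criterion does not reliably separate near-equivalent
  families: the four-parameter beta can mimic nearly any bounded unimodal
  shape, logistic is close to normal, and gamma is close to log-normal.  The
  family-recovery test therefore simulates from families that are mutually
  identifiable within the candidate set (beta, log-normal, logistic); for
  prior *sampling* quality the chosen family's density matters, not its
  label.
* Prior samples double as data augmentation: `k` samples per training image
  pair the same image with different prior guesses.  The default is `k = 25`;
  the study's own arithmetic on this point is internally inconsistent
  (25 samples per image on 1,970 training images versus a stated total of
  10,050 pairs, which corresponds to 402 images), so `k` is exposed as a
  parameter.

## Component 2 — convolutional refiner

No deep-learning framework is required: the network is a compact
depthwise-separable convolution stack written in numpy with hand-derived
backpropagation (gradients verified against finite differences), which keeps
the whole pipeline reproducible bit-for-bit under a fixed seed on any CPU.

* **Input encoding.**  The crop is resized to a fixed frame (default
  128×96 height×width; aspect distortion is accepted because keypoints are
  normalized), standardized to zero mean and unit variance, and concatenated
  with six unit-amplitude Gaussian heatmaps (σ = 3 px) centered on the prior
  keypoints — 7 channels total.  Heatmaps preserve the spatial structure of
  the prior guess for the convolutions, unlike a late-fusion vector
  concatenation.
* **Architecture.**  The model internally appends two normalized coordinate
  grids (x and y in [0, 1]) to the input so globally pooled features can
  carry positional information — a global-average-pooled translation-
  equivariant stack cannot regress coordinates otherwise.  Then `n_blocks`
  residual blocks (default 3, filters 32/64/128): separable conv → ReLU →
  separable conv → 2×2 average pool, plus a pooled pointwise shortcut, summed
  and activated.  Global average pooling, dropout, and a linear head follow.
* **Residual prior head.**  The head input is the pooled feature vector
  concatenated with the 12-value prior; its weights are zero-initialized and
  its output is *added to the prior*: `prediction = prior + Δ`.  An untrained
  refiner therefore reproduces the prior exactly, and training only has to
  learn image-conditioned corrections — the natural parameterization for a
  refinement stage and markedly more stable at small scale.
* **Training.**  Adam at learning rate 0.001, batch size 32, at most 5 epochs
  with early stopping (patience 2, best-validation weights restored), dropout
  0.5 after every block and on the pooled features but never on the output
  layer.  The loss is mean squared error over the 12 outputs; slots from
  unlabeled sides are masked out.  The validation split (20%) is made at the
  image level so augmented copies of one molar never straddle the split.
  Prediction runs with dropout inactive and clamps outputs to [0, 1].

## Component 3 — staging

Euclidean distances in pixel space after denormalization; no projection of
the crest onto the root axis.  A predicted crest coronal to the CEJ yields a
negative percentage and is clamped to 0; one apical to the apex is clamped to
100.  Band edges: 15% and 33% both belong to stage 2 (the neighboring bands
are strict inequalities).  Stage 3/4 is a single category, token `34`.  Roots
shorter than one pixel are flagged invalid rather than staged.  Physical
calibration is unnecessary since the percentage is a ratio.

## Evaluation scheme

Stage answers are scored one-vs-rest: each stage is a separate binary test
per item, giving TP/FN (items of that true stage) and FP/TN (the rest).
Metrics per stage: sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), F1 as the harmonic mean of sensitivity and precision, and the
study's "recall" — (TP+TN)/total, i.e. conventional accuracy — exposed as
`accuracy_recall` to avoid colliding with recall-as-sensitivity.  Every 0/0
ratio is defined as 0, matching the printed 0.000 entries.  Aggregates:
macro (unweighted mean), weighted (support-proportion weights), micro
(metrics recomputed on counts pooled over the three binary tests; micro
sensitivity then equals plain multiclass accuracy).  The published
weighted-average rows are not consistent with support-proportion weighting
of the published per-stage values (nor any standard weighting we could
identify), so weighted aggregates are reported but not validated against the
publication.  Display rounding is 3 decimals, half-up.

Rater self-consistency uses ICC(2,1): two-way random effects, absolute
agreement, single rater, computed from the two-way ANOVA mean squares and
cross-checked against `pingouin.intraclass_corr` (type ICC(A,1)).  The
published 0.91 does not state its ICC form; absolute agreement on single
ratings is the strictest standard choice for a test–retest design.

## Synthetic molar generator

The generator renders stylized, not photorealistic, crops: a bright crown
plus two divergent tapered roots over a darker background, and an additive
bone band whose upper boundary passes through both crest keypoints (bone
overlays roots, as in a projection radiograph).  The crest keypoint is placed
*on* the CEJ→apex segment at the fraction that realizes a PBL percentage
sampled inside the target stage's band, so emitted keypoints realize the
target exactly by construction; Gaussian noise (σ = 6 intensity units), blur
(σ = 0.7 px) and ±15% contrast jitter are applied afterwards.  Mesial and
distal percentages are drawn with correlation 0.7 through a Gaussian copula
(bone loss is correlated across a tooth).  Stage frequencies default to the
study mix 57.14% / 35.71% / 7.14% (= 48/84, 30/84, 6/84); per-stage sampling
bands (2–13, 17–31, 35–60) keep a 2-point margin from the 15/33 boundaries so
labels stay unambiguous.  Half the crops are emitted apex-up as upper-jaw
molars, so the orientation step is exercised.

What the generator does *not* emulate: obstructive factors (crowding,
restorations, over/under-exposure), anatomical variation beyond box geometry
and bone level, missing labels, and detector physics.  Passing tests
therefore demonstrate geometric and statistical correctness of the pipeline,
not clinical performance on real radiographs.

## Problem sizes and numerical choices

Desk-scale experiments (tests and the acceptance script) train a 3-block
refiner with filters 16/32/64 on a 64×48 input, 300 training crops, 6 prior
samples per image and the default 5 epochs — sized so a full run completes in
minutes on one CPU core while still demonstrating that refinement beats the
raw prior on held-out stage accuracy (0.54–0.71 across desk runs versus
~0.42 for the prior, whose samples scatter around the population-mean bone
level near the stage-1/2 border).  Longer
training (15 epochs at the same scale) drives held-out keypoint error to
about 64% of the prior's, which is what the keypoint-error dominance test
exercises at a 32×24 input.  Adam uses β = (0.9, 0.999), ε = 1e-8; separable
convolutions use He-normal initialization; average pooling truncates odd
trailing rows/columns; degenerate standard deviations in image normalization
fall back to 1.

## Known limitations

* The refiner is desk-scale; no attempt is made to reproduce the original
  GPU-scale network or its (unpublished) validation loss.
* Molar detection on uncropped panoramic radiographs is out of scope; inputs
  are pre-cropped boxes.
* The prior treats coordinates as independent; correlated priors (e.g. a
  joint shape model) would propose more anatomically coherent guesses.
* Stage-3/4 support in the default mix is small by design (it mirrors the
  study population), so per-stage metrics for that class are high-variance
  on small synthetic test sets.
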