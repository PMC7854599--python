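# Methods

## The grading model

Fouling severity is treated as ordinal regression: the network emits one
real score trained against the SLoF class index (0, 1, 2) rather than a
softmax over classes, so the loss magnitude reflects how far a mistake
is on the severity scale.  Losses are mean squared error or smooth-L1
(0.5r² for |r| < 1, |r| − 0.5 otherwise), each sample weighted by
w_c = N/(K·n_c) computed from the class counts of the training portion
of its fold only; with these weights the total contribution of each
class equals what a balanced dataset would give (Σ n_c·w_c = N).

The scorer is a deliberately small convolutional network implemented in
numpy with manual backpropagation: a 5×5 convolution with 8 filters,
ReLU, 4×4 average pooling, a 32-unit fully connected layer, and a linear
output.  A `linear` architecture (linear map on 8×8 mean-pooled pixels)
serves as a floor baseline.  Optimisers: SGD with momentum and AdamW;
schedules: multistep decay, cosine annealing, one-cycle; augmentation:
`basic` (flips plus padded random crops) or `complex` (adds right-angle
rotations and brightness/contrast jitter), all label-preserving.  The
`freeze_batch_norm` flag is accepted for configuration compatibility but
is a no-op: the numpy networks deliberately carry no batch-normalisation
layers, which are the layers one would keep frozen when fine-tuning a
pretrained backbone on a modest dataset.  Training is single-threaded
and a pure function of the configuration seed; identical configurations
reproduce identical score files.

Defaults (48×48 inputs, batch 64, AdamW at 3e-3 with cosine annealing
for 24 epochs, smooth-L1, weight decay 1e-4) were chosen as the smallest
budget at which the network reliably learns the synthetic fixture —
out-of-fold mean AP above 0.9 and a Spearman correlation of at least 0.8
between held-out scores and true coverage across seeds.  Larger
pretrained backbones at 512×512 remain a configuration direction, not
something the desk-scale pipeline depends on.

Cross-validation is 5-fold and grouped by vessel, since all images of a
vessel share coating, lighting and fouling-community style; folds are
filled greedily (largest vessel first, seeded order) into the currently
smallest fold, breaking ties towards the fold whose class mix the vessel
best restores.  This keeps per-fold class proportions within a few
points of the global mix without ever splitting a vessel.  Ensembling
averages raw scores; the exhaustive best-subset search is limited to 20
members.  Hyperparameter candidates can be drawn from a scrambled Sobol
sequence over linear- or log-scaled bounds; the search is provided as a
tool and not wired into the default pipeline.

## Thresholding

A prediction is positive when score ≥ threshold (closed lower bound).
The PR curve has one point per distinct score, in descending order, so
tied scores collapse to a single point and recall is non-decreasing.
Average precision uses step interpolation with R₀ = 0 — no 11-point or
trapezoidal smoothing.  Threshold selection maximises precision subject
to the recall floor (50/80/95% policies), with precision ties broken
towards the larger threshold; because the feasible set grows as the
floor drops, a lower recall target can never select a less precise
operating point.  Thresholds are chosen once on the combined out-of-fold
validation curve and then frozen for the test split.  When the two
per-task cutoffs are combined into a 3-class prediction, the heavy rule
takes precedence (score ≥ heavy cutoff → SLoF 2 regardless of the
fouling cutoff), with a warning if the cutoffs cross.

## Benchmarking against experts

Label pairs are ordered: with k raters over n images the within-group
construction yields n·k·(k−1) pairs and the candidate-vs-group
construction n·k, the group member always on the reference (truth) side.
Because every unordered pair appears in both orders, the group pairing
makes per-task precision and recall identical by construction.
Agreement, precision and recall are computed after collapsing grades per
task; all proportions carry Wilson score intervals (chosen for good
behaviour near 0 and 1).  Pairs are pooled over images even though the
pairs sharing an image are dependent; an image-level cluster bootstrap
(1,000 seeded resamples) is available as a cross-check on the pooled
interval.

The Fisher exact test is two-sided with the point-probability rule
(tables whose hypergeometric probability is ≤ observed × (1 + 1e-7) are
counted, the convention of the standard R implementation), evaluated in
exact integer arithmetic; the reported odds ratio is the sample
(a·d)/(b·c).  Non-inferiority uses the operative one-sided bound of a
TOST pair for two proportions: unpooled Wald standard error, no
continuity correction, z = (d − margin)/SE with d the reference-minus-
candidate agreement difference and a 0.05 margin; p = Φ(z), rejected at
α = 0.05.  The opposite TOST bound is vacuous for this hypothesis and is
not reported.  With a degenerate standard error the p-value is exact 0,
1 or 0.5 and flagged.

## Synthetic data

The generator emulates the structure of restricted hull-survey data:

- **Coverage → grade rule.**  Coverage is rounded to the nearest integer
  percent, then banded (0 → SLoF 0, 1–15 → 1, ≥16 → 2).  Rounding first
  makes the band edges exact and the rule total on [0, 1].  Class-0
  coverage is fixed at 0: slime is rendered as background texture, never
  as mask pixels, matching a scale whose lowest grade tolerates biofilm.
- **Images.**  One style per vessel (base coat colour, plate seams,
  lighting gradient, turbidity blur, colour cast, organism texture).
  Fouling is placed by rejection-sampling textured ellipses, centres
  biased to uncovered hull, radius capped near the remaining deficit,
  until achieved coverage is within ±0.5 percentage points of target
  (iteration cap 10,000, then a generation error naming the constraint).
  The mask's positive fraction *is* the achieved coverage, exactly.
  Images are 8-bit RGB PNG, 256×256 by default (64×64 in the demo to
  stay desk-scale); per-image random streams derive from a SHA-256 hash
  of (master seed, image id), so generation is order-independent and
  byte-reproducible.
- **Manifests.**  Per-class counts are met exactly; class-1 coverage is
  uniform on the 1–15% band, class-2 on 16–100%.  Defaults reproduce the
  published survey arithmetic: 10,263 images (7,822/1,696/745 per
  grade), an 841-image test region (494/193/154) on 14 dedicated test
  vessels of which a SLoF-stratified 120-image subset forms the
  expert-group split, and 286 training vessels.  A manifest-only mode
  skips rendering so full-scale structure checks run in seconds; the
  "image file exists" guarantee applies only when rendering is
  requested.
- **Raters.**  Each simulated expert is a 3×3 confusion profile; labels
  are conditionally independent draws given the true grade.  The default
  profiles are near-certain on SLoF 0 and 2 and noisier on SLoF 1
  (≈78% correct), reproducing the observed pattern that experts agree
  most on clean or heavily fouled hulls.  The analytic pairwise
  agreement Σ_t π_t Σ_o A[t][o]·B[t][o] is the calibration oracle for
  the simulator.
- **Scores.**  Simulated raw scores are true grade plus Gaussian noise,
  for exercising thresholding and benchmarking without training.

What the synthetic data does **not** emulate: real organism morphology,
species composition, scale ambiguity, motion blur, niche-area geometry,
or label noise that depends on image quality rather than true grade.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and calibrated, not that the CNN would reach any particular
accuracy on real survey imagery.

## Numerical and design notes

- Fisher p-values are exact rational arithmetic cast to float once; the
  test suite checks them against an independent implementation to 1e-12
  on every table with margins ≤ 12.
- Wilson interval endpoints are snapped to exact 0/1 at degenerate
  counts (x = 0 or x = n), where those values are analytically exact.
- Manifest and score CSVs are written with `%.17g` and parsed in
  round-trip mode so floats survive the file boundary bit-for-bit.
- Precision or recall with a zero denominator is reported as undefined,
  never silently zero.
- Desk-scale problem sizes: the reference demo uses 600 images over 30
  vessels with a 150-image test region and a 60-image expert group;
  unit tests use a 200-image fixture.  These sizes were chosen so the
  full suite exercises every stage, including training, in minutes on
  one CPU.

## Known limitations

- The numpy CNN is intentionally tiny; it demonstrates the training
  contract (weighted ordinal regression, grouped CV, ensembling) rather
  than state-of-the-art accuracy, and there is no GPU path.
- The non-inferiority test is asymptotic; at very small pair counts its
  boundary type-I error drifts from the nominal level (the suite checks
  calibration at the study's pair counts, 720/360).
- Pooled Wilson intervals understate uncertainty when many pairs share
  an image; use the cluster bootstrap for a dependence-aware interval.
- The expert-group subset is stratified across SLoF; the original study
  stratified across a finer six-class scheme unavailable here.
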