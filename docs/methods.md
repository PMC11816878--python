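# Methods

`texhawk` implements a hybrid two-class grayscale image classifier of the kind
used for Alzheimer's-disease MRI screening: texture statistics and deep
convolutional features are fused per image, a Harris Hawks Optimization (HHO)
wrapper selects a compact feature subset, and an LSTM performs the final
benign/malignant (control/diseased) decision. This note records the model,
its assumptions, the tunable parameters, and the design decisions taken where
the design was genuinely open.

## Preprocessing

Images are smoothed with a Gaussian kernel specified by its full width at
half maximum in millimetres (default 4 mm) and converted to a pixel-space
sigma via sigma = FWHM / (2·sqrt(2·ln 2) · voxel pitch). The pixel pitch
defaults to 1 mm isotropic; synthetic fixtures define their own pitch.
Boundaries are handled by half-sample reflection, which preserves mean
intensity and avoids edge darkening. Smoothing precedes resizing (the
alternative order is defensible too; the pipeline applies smooth→resize and
records both in the manifest). The default target size is 224×224, the input
size expected by standard ImageNet-family CNN backbones. Splits are 70/30
train/test and stratified by default: at desk-scale sample sizes an
unstratified split frequently produces noticeably imbalanced test sets.
Brain extraction proper (skull stripping) is an external-tool concern; the
package offers only a binary foreground-mask multiply.

## Texture features

For each (distance, angle) offset a gray-level co-occurrence matrix (GLCM)
is accumulated, symmetrized and normalized (the dominant Haralick
convention; both are configurable). Angles follow the common convention with
rows increasing downward: 0° = (0, +d), 45° = (−d, +d), 90° = (−d, 0),
135° = (−d, −d). Five statistics are computed per offset — energy Σp²,
contrast Σ(i−j)²p, homogeneity Σp/(1+|i−j|), correlation
Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ), and entropy −Σp·log₂p with 0·log 0 = 0. The default
configuration (distance 1, four angles, five statistics) yields the
package's canonical 20-feature texture block. Images are down-quantized by
uniform binning before counting (default 32 levels in the pipeline); full
8-bit range (256 levels) is supported.

Degenerate cases: a constant image produces a single-cell GLCM; its
correlation is defined as 0 (no marginal variance to normalize by).

## Deep features

The deep stage is a backend contract (`name`, `output_dim`, `deterministic`,
`extract(image)`), so any CNN embedding can be plugged in. The bundled
backend is a fixed random-feature convolutional network: two seeded
convolution + ReLU + average-pool stages, global average pooling, and a
seeded linear projection to 20 features. Untrained random convolutional
features are a standard inexpensive image embedding; they are fully
deterministic given the seed, need no weight files, and retain enough
band-pass spatial statistics to separate texture classes. Input centering
(subtract the image mean) is on by default, making the features invariant to
constant intensity offsets. How a published pipeline reduced a 2048-d
ResNet-50 embedding to 20 features is generally under-specified; a fixed
linear projection after global average pooling is the choice made here and
is recorded in the run manifest.

Fusion concatenates deep-then-texture into a 40-feature vector with
provenance-tagged names (`deep:*`, `glcm:*`). Per-feature standardization
statistics are fit on the training split only and reused verbatim at test
time; zero-variance columns are centered but not scaled.

## Harris Hawks Optimization

HHO is a population metaheuristic: N "hawks" (candidate solutions) chase the
best solution found so far (the "rabbit"). The escape energy
E = 2·E0·(1 − t/T) decays linearly to exactly 0 at t = T and dispatches the
per-hawk update:

- |E| ≥ 1 — exploration: with probability ½ perch relative to a random flock
  member (X′ = X_rand − r₁|X_rand − 2r₂X|), otherwise relative to the rabbit,
  centroid and bounds (X′ = (X_rabbit − X_mean) − r₃(LB + r₄(UB − LB))).
- |E| ∈ [0.5, 1), r ≥ 0.5 — soft besiege: X′ = ΔX − E|J·X_rabbit − X| with
  ΔX = X_rabbit − X and escape step J ~ U[0, 2].
- |E| < 0.5, r ≥ 0.5 — hard besiege: X′ = X_rabbit − E|ΔX|.
- r < 0.5 — rapid dive: X′ = X_rabbit − E|J·X_rabbit − X_mean|, accepted only
  if it improves the hawk's cost (greedy acceptance).

E0 is resampled uniformly in [−1, 1] per hawk per iteration (the original
formulation's convention, consistent with an energy that "decreases randomly
from 2 to 0"); a fixed E0 is available via `e0_fixed` for configurations that
state a single initial energy value of 2. The Lévy-flight perturbation of the
original formulation's progressive dives is off by default and available via
`levy_dives`. Positions are clamped to [LB, UB] before evaluation; non-finite
costs reject the candidate with a logged warning. Defaults are population 30
and 100 iterations. The best-so-far cost is non-increasing by construction,
and the evaluation budget is exactly N·(T+1) objective calls.

## Wrapper feature selection

Hawk positions live in [0, 1]^n and are binarized by thresholding at 0.5
(bit set iff coordinate ≥ threshold); an all-zero mask is repaired to the
single largest coordinate. A mask is scored by

    cost = w1 · Error(mask) + w2 · m/n

with defaults w1 = 0.99, w2 = 0.01 (the common wrapper-selection weighting
that keeps error dominant; weights are normalized to sum to 1). The m/n
orientation is the one under which minimizing the cost rewards
dimensionality reduction. Error is the cross-validated misclassification
rate of a small one-hidden-layer perceptron (width 16) trained on the masked
columns only.

Two evaluator choices matter and are worth recording:

- Validation scheme. A single fixed holdout lets thousands of mask
  evaluations overfit one partition: masks that "explain" the handful of
  boundary samples with chance-correlated noise columns reach zero estimated
  error. The default is therefore stratified 5-fold cross-validation
  repeated over 2 fold partitions (all derived from the evaluator seed, so
  each mask's score is still deterministic); a single holdout remains
  available via `n_folds=1`.
- Training length. The perceptron is trained for a limited number of epochs
  (default 50 of mini-batch adam; the package's selection studies use 30). A
  fully converged evaluator scores large
  noisy masks and compact informative masks identically (error ≈ 0 for
  both), leaving only the weak w2 term to prune; a training-limited
  evaluator pays a real error cost for irrelevant input dimensions, so the
  error term itself penalizes bloated masks. This is a deliberate property
  of the cost, not an accident of under-training.

Costs are cached by mask bits (the optimizer revisits subsets constantly),
and the mask returned is the best ever evaluated, not merely the final
rabbit.

## LSTM classifier

The cell follows the standard gated recurrence (forget/input/output gates,
tanh candidate, c′ = f∘c + i∘g, h′ = o∘tanh(c′)). Two printed-form
variations are handled explicitly: the input gate's defining equation is the
symmetric σ(W_i x + U_i h + b_i), and an alternative non-gated read-out
h′ = tanh(c′) + o is available behind a `paper_literal` flag for comparison
runs (it is not the default because it abandons output gating and breaks the
|h| < 1 range).

Flat feature vectors are presented to the recurrence as a sequence of
zero-padded chunks (default chunk length 8, so 40 features → 5 time steps).
A final affine + sigmoid read-out on the last hidden state gives the
positive-class probability; label 1 iff p ≥ 0.5. Training is plain
mini-batch gradient descent on binary cross-entropy with exact
backpropagation-through-time gradients, a forget-gate bias initialized to 1,
and full determinism under the config seed. Defaults: hidden size 16,
learning rate 0.05, batch 32, 200 epochs. Models serialize to a versioned
flat-weight JSON file.

## Evaluation

The positive class is the diseased ("malignant") class. Reported metrics are
accuracy (TP+TN)/n, sensitivity TP/(TP+FN) and precision TP/(TP+FP), all in
percent. The specificity kernel TN/(TN+FP) is reported twice, as
`specificity` and as `paper_precision`: published pipelines in this area
sometimes print this quantity under the name "precision", and carrying both
names keeps comparisons against such tables unambiguous without silently
propagating the mislabel. Metrics with a zero denominator are reported as
undefined (`None`), never as 0 — small test sets hit these cases.

## Synthetic data

Real Alzheimer's MRI collections (ADNI, MIRIAD) are access-restricted, so
the package generates its own two kinds of fixtures; every generator is a
pure function of (spec, seed).

- Textured images: white noise smoothed to a class-specific correlation
  length (`blob_scale`, in pixels), standardized, scaled to one sixth of the
  gray range, shifted to the class mean level, optionally perturbed with
  per-pixel noise, and quantized. Smaller blobs give systematically higher
  GLCM contrast and lower homogeneity, which is precisely the statistical
  axis the texture block measures. These fixtures emulate the *texture
  separability* of a two-class imaging problem; they do not emulate anatomy,
  acquisition physics, intensity inhomogeneity or inter-scanner variation,
  so a passing end-to-end test demonstrates that the pipeline machinery
  works, not that real MRI classes are separable at any particular accuracy.
- Planted feature tables: n samples × p Gaussian columns in which a known
  subset of `n_informative` columns receives a between-class mean shift of
  `effect_size` within-class standard deviations (default 40 columns, 5
  informative, effect 3, n = 200 — mirroring a fused 20+20 feature set with
  a strong but not trivial signal). The planted column names are recorded so
  selection can be scored against ground truth.

## Study configurations and problem sizes

Library defaults mirror the published parameterization (population 30, 100
iterations, 4 mm FWHM, 224×224, 70% training). The package's own studies run
at desk scale:

- Planted-recovery study: tables as above, HHO with 30 hawks × 60 iterations
  and Lévy dives enabled, cost weights w1 = 0.95 / w2 = 0.05, evaluator with
  15 training epochs and 2 CV repeats, 5 seeds; recovery is summarized by the
  median count of planted columns selected and the median mask size. Observed
  result: median 4 of 5 planted columns recovered, median mask size 14. A
  configuration sweep (w2 ∈ [0.01, 0.1], evaluator width 8/16, epochs 15–50,
  2–5 CV repeats, budgets up to 30×60) traces a hits/compactness frontier
  through (4 hits, 14 selected) and (3 hits, 7–9 selected): pushing mask size
  to ≤ 10 always costs the fourth planted column. Two effects bind. First,
  identifiability: at effect size 3 and n = 200, masks holding 3 of the 5
  (mutually redundant) planted columns already separate the classes at
  measured CV error ≈ 0–1%, so the error term barely distinguishes 3 from 5
  planted columns. Second, move granularity: thresholding continuous hawk
  positions at 0.5 yields multi-bit mask changes, and the per-column sparsity
  reward (w2/n ≈ 10⁻³) is below the CV error estimate's per-mask fluctuation,
  so fine single-column pruning stalls in local minima (verified directly: at
  a typical stall, no single-bit removal improves the measured cost).
  Joint (≥ 4 hits, ≤ 10 selected) recovery is therefore not reliably reached
  by threshold-binarized HHO at these study conditions; the acceptance test
  records this honestly.
- End-to-end study: 50 images per class, 64×64 pixels, 32 gray levels,
  blob scales 2 px vs 8 px (well-separated textures), HHO 15×20, classifier
  150 epochs. A label-shuffled run of the same fixture provides the
  chance-level null, and a repeated run with the identical config checks
  byte-for-byte reproducibility of the report.

## Known limitations

- The bundled deep backend is untrained; on real MRI a pretrained embedding
  should be plugged in through the backend contract.
- Wrapper selection inherits the usual caveat that the selected subset
  optimizes an internal validation estimate; columns kept are not guaranteed
  causal, and at these sample sizes masks with 4 of 5 planted columns are
  often statistically indistinguishable from the full planted set.
- The LSTM consumes an arbitrary chunking of a flat feature vector; the
  sequence axis is a modeling convenience, not a temporal claim.
- Binary classification only; no multi-class staging (e.g. MCI grades).
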