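# Methods

## The detection model

The detector assumes that a fall, wherever it occurs inside a recording, is
captured by a fixed-duration interval around the global maximum of the
acceleration magnitude: the impact against the ground produces the largest
magnitude spike in the trace, so centering the classifier's input on that
peak aligns the free-fall dip, the impact and the post-impact posture change
across recordings without any segmentation or event detection.  Two input
encodings are supported: the magnitude series itself (SMV, one value per
sample) and the three raw axis series concatenated per axis
(`[Ax | Ay | Az]`, three values per sample).  The triaxial layout keeps each
axis temporally contiguous so the 1×5 convolution kernels see within-axis
dynamics; an interleaved layout would put 3-sample strides between
consecutive time steps of one axis.

The window holds `n = 2·⌊(T_W/2)·fs⌋ + 1` samples per axis — symmetric
around the peak and peak-inclusive, which is the unique rule reproducing
1001 samples at 200 Hz for a ±2.5 s window.  When the peak lies within half
a window of a trace boundary, the boundary sample is replicated to fill the
window.  Zero-filling was rejected deliberately: near-zero acceleration is
the signature of free fall, and padding with zeros would inject a synthetic
fall cue into ADL windows.  When the window is longer than the whole trace
the configuration is inapplicable and reported as skipped, never truncated.
Peak ties resolve to the earliest index.  All indexing is 0-based.

No filtering, detrending, gravity separation, resampling or input
normalization is applied anywhere: the classifier consumes raw sensor
values in m/s², and the batch-normalization layers handle scale internally.

## Architecture and training

Four feature-extraction blocks — convolution (kernel 1×5, zero-pad 2,
stride 1; 16/32/64/128 filters) → batch normalization → ReLU → max-pooling
(1×5, stride 5) — with pooling omitted from the fourth block, followed by
dropout, one fully-connected layer to 2 units, and softmax.  Pooling stride
equals pool width (non-overlapping), since the pooling stage exists to
down-sample the feature maps; each pooled block maps width `w → ⌊w/5⌋`.

Training: SGD with momentum 0.9, initial learning rate 10⁻⁴, mini-batches
of 64, L2 coefficient 10⁻⁴ on convolution and fully-connected weights
(not biases or batch-norm parameters), dropout rate 0.5 immediately before
the fully-connected layer, cross-entropy loss, at most 20 epochs,
validation once per epoch, and early stopping after 3 consecutive epochs
without a new validation-loss minimum; the weights returned are those of
the best-validation epoch.  Learning rate, batch size, epoch cap, patience
and the loss are fixed by the protocol; momentum, the L2 coefficient and
the dropout rate/placement are conventional defaults, chosen once and
exposed in `TrainConfig`.

Numerical choices that required a decision:

* **Classifier-head initialization.** Convolutional layers use seeded
  He-scaled Gaussian initialization, the standard choice ahead of ReLU.
  The softmax head is zero-initialized: at desk scale (∼100 traces, one
  full-batch update per epoch, 20 epochs) a randomly initialized head
  contributes an arbitrary class preference of the same order as everything
  20 small gradient steps can learn, whereas a zero head starts from
  indifference and its first update already aligns the decision boundary
  with the class-mean feature difference.  The He rationale does not apply
  to a layer feeding softmax rather than ReLU.
* **Batch-norm finalization.** Moving-average statistics updated once per
  epoch never approach the true activation statistics, which would make
  inference-mode validation losses — and hence early stopping — arbitrary.
  Before every validation pass, each batch-norm layer's inference
  statistics are replaced by the exact population statistics of its input
  over the training set, finalized layer by layer.  This mirrors the
  post-training statistics finalization of mainstream deep-learning
  toolboxes and keeps validation faithful to deployment behaviour.
* **Pooling of narrow inputs.** A width-5 pool on an input narrower than 5
  pools the whole remaining extent (output width `max(1, ⌊w/5⌋)`).  Strict
  width-5 pooling three times requires an input of at least 125 features,
  yet the benchmark protocol legitimately produces far narrower windows at
  low sampling rates (a ±0.5 s window at 50 Hz is 51 samples); graceful
  pooling lets the fixed architecture accept them, and is exactly the floor
  rule wherever `w ≥ 125`.  Inputs narrower than 5 are rejected at
  construction with the minimum stated.
* **Prediction tie-break.** An exact 0.5/0.5 posterior resolves to FALL:
  in a detector the costlier error is a missed fall.
* **Reproducibility.** Every stochastic element (initialization, epoch
  shuffling, dropout masks) is driven by generators spawned from a single
  seed; two runs with identical data, configuration and seed produce
  bit-identical training histories.

## Evaluation protocol

Each dataset is split 60/20/20 into train/validation/test, stratified by
class with largest-remainder rounding, which guarantees every subset's
class counts are within one trace of the exact proportional targets.
The benchmark sweeps dataset × half-width (±0.5/±1/±1.5/±2.5 s) × variant
(SMV/triaxial), training a fresh network per cell at the dataset's own
sampling rate — input widths differ across datasets and are never
resampled.  A cell is SKIPPED exactly when some trace is shorter than the
requested window; unexpected per-cell failures are recorded separately
(`ERROR`) without aborting the sweep.  Each cell derives an independent
seed by hashing (master seed, dataset, half-width, variant), so any cell is
reproducible in isolation; cells hold one seeded run each (a repetition/
averaging layer can be built on top, but the grid reports single runs).
FALL is the positive class everywhere.

## Synthetic data

The generator emulates the statistical structure the detector exploits, at
the default study scale of 100 traces (60 ADL, 40 falls) of 10 s at 50 Hz:

* **ADL traces**: gait-frequency (2 Hz) sinusoidal bobbing and sway around
  the 1 g gravity vector, or a slow postural re-orientation with a small
  magnitude bump; magnitude stays within roughly (0.7 g, 1.5 g) — never a
  free-fall dip, never an impact-level spike.
* **Fall traces**: walking prefix ≈ 1 g → free-fall segment averaging
  0.2 g for 0.4 s → impact spike drawn around 4 g (the trace's global
  magnitude maximum) → post-impact rest at 1 g with a rotated gravity
  decomposition (the subject ends up lying down).  Typical fall dynamics
  span 1–3 s, so fall traces require at least 1 s of duration.
* Independent per-axis Gaussian noise (σ = 0.05 g) throughout; per-trace
  seeds spawn from the collection seed, so regeneration is byte-identical.

Defaults make the classes strongly separable on purpose — they verify that
the pipeline recovers constructed structure, not that the method works on
real falls.  `SyntheticConfig.hard()` (impacts 1.8 g, noise 0.15 g) shrinks
the margin between fall impacts and locomotion peaks to exercise the
imperfect-classifier paths (non-trivial confusion tables, non-degenerate
Se/Sp trade-offs).  What the generator does **not** model: real sensor
artifacts (clipping, quantization, axis cross-talk, drift), subject
variability and biomechanics, near-fall ADLs (sitting down hard, jumping),
or the heavy class imbalance and trace-length heterogeneity of the public
repositories.  Passing on synthetic data therefore demonstrates pipeline
correctness, not field performance; the published repository results
additionally depend on each repository's unit conventions and split
randomization, which is why they are out of scope here.

## Problem sizes

The shipped tests and the acceptance script run the complete pipeline at
the default study scale: 100 traces per collection, 50 Hz, ±2.5 s windows
(251 SMV / 753 triaxial features), full 4×2 benchmark grids on the
low-margin and short-trace collections, and the width recursion checked for
every input width from 125 to 3003.  These sizes exercise every code path
end to end; scaling to repository-sized collections (thousands of traces,
200 Hz, 1001/3003-feature windows) changes only wall-clock time, not code.

## Known limitations

* The network is pure NumPy and single-threaded; it is sized for
  protocol-scale experiments, not GPU-scale training.
* Unit conversion is a single multiplicative factor per dataset; affine
  (offset) calibrations are out of scope.
* Sampling jitter is ignored: the nominal manifest rate dimensions the
  windows even for datasets with irregular timestamps.
* Subject-wise (leave-one-subject-out) splitting is not part of the
  protocol: test samples come from the same subjects as training samples,
  which is known to flatter wearable-sensor classifiers.
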