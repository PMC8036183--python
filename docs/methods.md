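# Methods

## Problem

Visual reading of amyloid PET scans classifies a brain as amyloid-negative
(clear grey/white-matter contrast: cortical uptake well below the high
non-specific white-matter retention) or amyloid-positive (cortical tracer
binding elevated, eroding that contrast). `amycnn` implements the full
computational pipeline for learning this dichotomy from scans: SUVR
quantification from dynamic PET, slice-based 2D convolutional networks per
anatomical axis, stratified cross-validation with tri-plane majority
voting, and class activation mapping for localization. A built-in dynamic
phantom generator provides labelled, spatially aligned cohorts so the whole
pipeline is testable without patient data.

## SUVR quantification

A dynamic scan is a 4D activity volume with a contiguous frame schedule.
The reference time-activity curve (TAC) is the per-frame unweighted mean
over a binary cerebellar grey-matter mask. The SUVR image over a window
[t0, t1] (default 50-70 min post-injection) is

    SUVR(v) = <A(v, f)>_w / <TAC(f)>_w

where `<.>_w` is the duration-weighted mean over frames whose intervals lie
entirely inside the window. Frames partially overlapping the window are
excluded (with a warning) rather than fractionally weighted; if the
included frames cover less than 95% of the window, the computation refuses
to proceed. Because numerator and denominator use identical frames, SUVR is
invariant under global rescaling of the activity (decay, dose, units).

Spatial alignment is assumed done upstream: every operation requires
identical grids and never resamples. Brain masking zeroes voxels outside
the union of grey- and white-matter masks. Average templates are plain
voxelwise means of aligned SUVR images.

## Phantom

Geometry is three concentric/adjacent ellipsoids defined in grid fractions:
a cortical grey-matter shell around a white-matter core, plus a separate
cerebellar grey-matter blob below and behind the brain, which serves as the
reference region. Realistic anatomy is deliberately out of scope — the
classifier only needs class-dependent grey/white contrast.

Kinetics are a saturating plateau, `a_r(t) = A_ref * S_r * (1 - e^{-t/tau})`
with `tau` = 10 min, so the 50-70 min window sits >99% onto the plateau and,
because the temporal shape is shared by every region, the windowed ratio to
the cerebellar reference equals the per-scan SUVR target `S_r` *exactly* in
the noise-free case (the parameter-recovery tests assert 1e-6 relative
error). Defaults: cortical SUVR 1.0 (negative class) vs 1.6 (positive),
white matter 1.7 (non-specific white-matter retention is high for amyloid
tracers, giving negatives their strong contrast), cerebellum 1.0 by
construction, plateau activity 20 kBq/mL, 2 mm voxels. The default frame
schedule is the 29-frame protocol 1x15, 3x5, 3x10, 4x60, 2x150, 2x300,
4x600, 10x300 s; any consistent schedule covering the window is accepted.

Per-scan biological spread is additive Gaussian jitter on the cortical and
white-matter targets (`between_subject_sd`, default 0.05); voxel noise is
multiplicative Gaussian per voxel per frame (`noise_cv`, default 0.05) —
a scale-free stand-in for PET's proportional noise, not a Poisson count
model. What the phantom does **not** emulate: anatomy, partial-volume and
resolution effects, motion, misalignment, kinetic heterogeneity. Passing
tests therefore demonstrate the pipeline's correctness and its behaviour
under the intended contrast structure, not clinical performance.

The default generator grid is the processed-data grid 79 x 95 x 68 at
2 mm; tests and the reproduction script use 32 x 32 x 16 to keep runtimes
in minutes on one CPU. Default cohort compositions are 101/32
(train/validation) and 13/9 (external test), an imbalanced early-stage
screening population.

## Data preparation

Each scan's masked SUVR volume is decomposed along one axis (sagittal /
coronal / axial); all slices of the scan form the channel dimension of a
single example, so each network emits one probability per scan. SUVR
values are clipped to [0, 3] and divided by 3 before the network (SUVR is
already a ratio scale; a fixed mapping avoids any per-scan or per-fold
statistics and hence any leakage). Class imbalance is handled by random
minority oversampling with replacement until counts are equal — applied
inside each CV fold to the training portion only, never to validation
data. Augmentation samples one in-plane affine transform per scan
(rotation within +/-10 deg, shift +/-10% of the field, shear +/-0.1, zoom
+/-10%, left-right flip with p = 0.5; "shear zooming" is read as two
separate operations) and applies it identically to every slice, since a
rigidly rotated head moves all slices together. Transforms are resampled
every epoch; interpolation is bilinear with zero fill. Augmentation is off
by default in `run_cv` and was not used for the reproduction runs — the
phantom cohort has no orientation variability to compensate.

## Network

Architecture (per decomposition):

    [conv(3x3, same) -> ReLU -> conv -> ReLU -> maxpool(2x2) -> batchnorm
     -> dropout(0.6)] x 2  ->  global average pooling  ->  dense(1, sigmoid)

Default filter counts are (32, 32, 64, 64); the test and reproduction
configuration uses (8, 8, 16, 16), which is ample for the phantom's
one-dimensional contrast. Training minimizes binary cross-entropy with
Adam (lr 1e-5, per-step decay `lr_t = lr / (1 + 1e-6 t)`, eps 1e-7) and a
batch size equal to the full training set: one optimizer step per epoch,
500 epochs by default, no early stopping. Everything stochastic is driven
by one seed; retraining is bit-reproducible.

Two design choices deserve explanation, both forced by the very low
learning rate. Adam's per-step parameter displacement is ~lr regardless of
gradient magnitude, so 500 full-batch steps move each parameter by at most
~5e-3; the decision boundary must therefore be essentially *correctly
centred from initialization*, with training building a small, clean class
separation around it.

1. **Batch-norm placement.** With batch norm ahead of ReLU inside the
   blocks, the features entering GAP are all-positive, and the dense
   weights' common-mode growth pushes both classes' logits in the same
   direction about an order of magnitude faster than the single bias can
   re-centre them — the threshold-0.5 accuracy then sticks at one class
   for any feasible epoch budget even when the logits rank the classes
   perfectly. Placing one batch norm per block *after* the max-pool makes
   the GAP features zero-mean per channel over the batch, so the logit
   distribution is centred at the bias (zero) and the fixed 0.5 threshold
   splits the classes as soon as any separation exists. The block then
   reads conv, ReLU, conv, ReLU, pool, batchnorm, dropout — the same
   components, ordered for trainability.
2. **Zero-initialized head.** The single sigmoid unit is initialized to
   zero weights and bias: a random head would impose an arbitrary initial
   logit offset of order 0.3 (an accidental class prior) that cannot be
   undone within the displacement budget, while a zero head starts every
   scan at probability 0.5 and needs no symmetry breaking. Convolutions
   use Glorot-uniform initialization as usual.

After training, each batch-norm layer's inference statistics are replaced
by the exact population statistics of its input over the training set (one
layer-by-layer sweep). The exponential moving average (momentum 0.99)
otherwise retains a ~0.99^epochs residue of its initialization, which is
larger than the class separation built at this learning rate.

Dropout (rate 0.6 after each pool) is active
only in training mode; inference is deterministic. The decision threshold
is fixed at 0.5.

## Evaluation

Stratified k-fold (default k = 5) partitions scans so per-fold class
counts differ by at most 1 from proportional; each class's remainder goes
to the currently smallest folds, so fold totals are also balanced (101/32
at k = 5 gives fold sizes 27, 27, 27, 26, 26 with 6-7 positives each).
Per-fold metrics are accuracy, sensitivity and specificity in percent;
a metric with a zero denominator is reported as undefined and excluded
from the cross-fold mean (with a warning), and the SD of a constant metric
is 0. Aggregation is mean +/- SD (ddof = 1) across folds. The best
decomposition is the one with the highest mean CV accuracy, ties broken by
sensitivity then specificity. Tri-plane majority voting thresholds the
three axis probabilities at 0.5 and takes the 2-of-3 vote, computed
per fold on held-out predictions. External-test prediction uses the
ensemble mean probability of the k fold models of the chosen axis
(configurable to a single model).

## Class activation maps

Because the head is GAP followed by one sigmoid unit, the logit decomposes
exactly: `logit = mean_xy( sum_n W_n f_n(x,y) ) + b` with `f_n` the final
pre-GAP feature maps. The raw CAM is that weighted sum at feature-map
resolution; its spatial mean plus the bias must reproduce the logit to
1e-5, which the tests use as a whole-forward-pass correctness oracle.
Negative values are kept (evidence for the negative class); min-max
normalization is applied only for display. Overlays are rendered on the
mid-stack slice by default, upsampled bilinearly.

## Numerical choices

- float32 forward/backward pass; float64 for SUVR ratios, TAC means and
  losses. im2col convolutions; 2x2 max-pool drops trailing odd rows/cols.
- Batch-norm eps 1e-3; Adam eps 1e-7, beta1 0.9, beta2 0.999.
- Oversampling and fold assignment use seeded PCG64 generators; per-scan
  phantom seeds are drawn from a master generator so cohorts are
  reproducible and individual scans regenerable.
- Degenerate inputs fail loudly: empty masks, uncovered windows, absent
  classes, grids too small for the brain layout, out-of-range
  probabilities.

## Reproduction problem sizes

The reproduction script (`scripts/acceptance.py`) and the heavier tests run
the cross-validation twin at grid 32 x 32 x 16 with filter counts
(8, 8, 16, 16) and 500 full-batch epochs — a deliberate scale-down chosen
so a full 5-fold run finishes in minutes on a single CPU while leaving the
training recipe (dropout 0.6, Adam 1e-5/1e-6, full batch) untouched.

## Known limitations

- The phantom's separability makes near-perfect CV accuracy expected; the
  pipeline's discriminative ceiling on real borderline scans is untested.
- The numpy network is CPU-only and full-batch oriented; it is not a
  general-purpose deep-learning stack.
- Per-epoch augmentation resampling recomputes the affine transforms in
  Python/scipy and dominates runtime when enabled with many epochs.
- Adam "decay" follows the legacy Keras per-update learning-rate decay
  convention, not weight decay.
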