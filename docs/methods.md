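# Methods

This note documents the models, numerical choices and study conditions
behind `scintibsi`: an automated Bone Scan Index (BSI) measurement
pipeline for paired anterior/posterior whole-body bone scintigrams.

## The measurement problem

Bone scintigraphy images the skeletal uptake of a Tc-99m-labelled
phosphonate tracer. Metastatic bone lesions appear as focal hot spots, but
so do benign conditions (fractures, osteoarthritis) and physiological
structures (kidneys, bladder). The BSI quantifies metastatic burden as the
percentage of total skeletal mass involved:

    BSI = 100 * sum_b  w_b * (metastatic hot-spot area in bone b) / (area of bone b)

where `w_b` is bone `b`'s mass fraction of the reference skeleton
(ICRP-derived). Computing it automatically requires (i) per-bone skeleton
segmentation and (ii) three-class hot-spot extraction (metastatic /
benign / everything else), both solved here with butterfly-type
fully convolutional networks that process the anterior and posterior views
jointly through a shared trunk.

## Pipeline

1. **Flip + alignment.** The posterior view is acquired mirrored; it is
   flipped about the vertical axis and rigidly translated to maximize
   body-mask overlap with the anterior view (exhaustive integer search via
   FFT cross-correlation of the masks, ±32 px).
2. **Spatial standardization.** The body mask's principal axis is rotated
   vertical, the head-to-toe extent is rescaled to correspond to 2000 mm at
   the configured output spacing, and the body is centered. The transform
   (one affine per view) is kept and inverted after inference with
   nearest-neighbour resampling.
3. **Grey normalization.** Per view, with φ the golden ratio and
   I10/I98 the intensities exceeded by 10% / 98% of body pixels:
   `out = ln(φ·(I−I98)/(I10−I98) + 1)` for `I > I98`, else 0. Percentiles
   are computed over the body mask only — background zeros would otherwise
   dominate them (the alternative, whole-raster percentiles, is the one
   genuinely open reading here).
4. **Skeleton segmentation.** The central crop of the standardized pair
   (default width 128 of 160 columns at desk scale) is resized to the
   network input shape and passed through a butterfly network with deep
   supervision; per-pixel argmax gives 13 anterior / 12 posterior classes
   (the posterior table has a dedicated rib∩scapula overlap class instead
   of the invisible sternum and clavicle).
5. **Hot-spot extraction.** The standardized pair is tiled into paired
   64×64 patches at stride 32, keeping patches that touch the body mask.
   A residual butterfly network emits 3-class logits per patch; at overlaps
   the *logits* are averaged (all covering patches — up to four with this
   geometry), then softmaxed. The decision rule, per pixel in order:
   metastatic if `p_meta ≥ th`; else non-malignant if `p_nonmal ≥ p_others`;
   else others.
6. **Threshold calibration.** `th` is the largest value for which the
   per-lesion sensitivity on the validation fold is ≥ 0.9, where a true
   8-connected lesion counts as detected when at least one of its pixels
   is labeled metastatic. Per-lesion maxima of `p_meta` are sufficient
   statistics, so the sweep runs over their sorted values. Calibration
   uses the validation fold so the test fold stays untouched (the original
   protocol does not state the calibration set).
7. **BSI.** Each 8-connected metastatic component is assigned to the bone
   holding the plurality of its pixels (components on pure background are
   excluded and reported). Per bone and view, ratio = hot-spot area / bone
   area (clipped to [0,1]); the rib∩scapula overlap class contributes half
   of its bone and hot-spot areas to each of rib and scapula, which keeps
   totals conserved. Bones visible in both views contribute the mean of
   their per-view weighted ratios; sternum and clavicle contribute their
   anterior value only. The total, ×100, is the BSI in percent.

## Networks

A butterfly network is two U-Net-style arms fused at the bottleneck: each
view has its own encoder; the deepest feature maps are concatenated into a
shared trunk; two decoders with same-view skip connections emit per-view
logits. Downsampling is by stride-2 convolution, upsampling by 2×2
stride-2 transposed convolution, each conv followed by batch norm and
ReLU. Variants:

- **DSV** (skeleton task): 1×1 side heads at the two finest intermediate
  decoder scales of each arm, nearest-upsampled to full resolution; the
  loss is the unweighted sum of the generalized Dice losses of all six
  supervised outputs against the full-resolution targets (one canonical
  target; side outputs are upsampled rather than targets downsampled).
- **Residual** (hot-spot task): every conv stage replaced by a two-conv
  residual block with identity shortcut (1×1 projection on channel or
  resolution change); a plain stem conv lifts the 1-channel input to
  `base_channels` so the first residual addition is well-typed.

The published architecture's exact channel widths are figure-only, so
depth and width are configuration: the full-scale profile uses depth 4 /
base 32 (skeleton) and depth 3 / base 32 (hot spots); the desk profile
uses much smaller instances (below).

The networks run on a small reverse-mode autodiff engine written on numpy
(`scintibsi.nn`): conv2d via channels-last im2col + GEMM, analytic
batch-norm backward, and closed-form loss gradients through the softmax.
Every operation is finite-difference checked in the test suite. Arrays
are float32 by default (float64 for gradient checks).

## Losses and training

- Skeleton: generalized Dice loss
  `1 − (2/C)·Σ_c (Σ_n p·t + ε)/(Σ_n p + Σ_n t + ε)` with ε = 0.001,
  summed over six outputs under DSV.
- Hot spots: class-weighted softmax cross entropy with
  `w_c = (N − Σ_n t_cn)/N` computed per batch — rare lesion classes get
  weight ≈ 1, the dominant "others" class ≈ 0. Natural log; probabilities
  floored at 1e-12 inside the log (the loss is undefined at 0 and the
  formulation is silent there).

He-initialized weights (variance 2/fan_in, zero biases); Adam with
α = 0.001, β₁ = 0.9, β₂ = 0.999, eps = 1e-8. The full-scale protocol is
batch 6 / 1620 iterations with α×0.1 at iteration 1350 (skeleton) and
batch 256 / 50 000 iterations with probability-0.5 paired horizontal-flip
augmentation (hot spots); checkpoints are selected at maximal validation
mean Dice and minimal validation misclassified pixels respectively (pure
argmax/argmin over the recorded series). Batches are drawn uniformly with
replacement. Validation cadence (unstated in the protocol) defaults to
every 30 / 500 iterations, configurable.

## Synthetic phantoms

The study's 246 clinical scans are not deposited, so all experiments run
on seeded synthetic phantoms. A stylized 2-D atlas draws 12 named bones
as ellipses, capsules and elliptical rings in body coordinates inside a
soft-tissue silhouette; the posterior view is rendered mirrored (as
acquired) with a small random acquisition shift, without sternum/clavicle
and with the rib∩scapula overlap class. Per case: pose (rotation ≤ 4°,
body height 86–94% of the raster, small jitter), 0–6 metastatic lesions
(disks of radius 0.010–0.022 body heights, +40–90 expected counts) placed
uniformly inside bones, 0–3 benign lesions (radius 0.008–0.016, +15–35
counts) placed preferentially at joints, kidney and bladder uptake in the
"others" class, soft tissue +7 counts over air 0.3, per-bone uptake
16–26 counts, and Poisson noise cast to 16-bit. Benign lesions are made
dimmer than metastatic ones — clinically, degenerative uptake is usually
less avid than metastases — which at desk scale is the main feature
separating the two lesion classes.

What the phantom does *not* emulate: collimator blur, scatter,
attenuation, 3-D overlap of anterior/posterior structures, patient-specific
anatomy, and lesion texture. Passing tests on phantoms therefore
demonstrates that the pipeline's machinery (geometry, losses, calibration,
scoring) is correct and trainable, not that clinical accuracy figures
would be reproduced.

The phantom's ground-truth BSI is computed by the very scoring module the
pipeline uses, from the truth rasters — so "oracle pipeline reproduces the
true BSI" is exact by construction, and any end-to-end discrepancy
isolates segmentation/extraction error.

The threefold cross-validation split mirrors the clinical protocol: cases
are shuffled into three equal groups; per fold two groups train and the
held-out group is halved into validation and test; each fold appears twice
with validation and test swapped (so six folds, and every case is tested).
With 246 IDs this yields 164/41/41.

## Desk-scale study conditions

All tests and the acceptance script run on one CPU, so the shipped desk
profile (`configs/desk.yaml`) uses: 320×160 rasters at 8 mm/px (2000 mm ≈
250 px), 60 phantom cases (≈ 2100 body patch pairs in total, ≈ 1400 in a
training fold), a
depth-3 / base-4 skeleton network on a 96×48 input (1100 iterations,
batch 4, decay at 900), and a depth-2 / base-6 residual hot-spot network
(900 iterations, batch 8). These sizes were fixed once as the package's
desk-scale conditions; the full-scale settings live in
`configs/paper.yaml` and are not exercised by the tests.

## Numerical choices and edge cases

- Raster convention: row-major, origin top-left, (row, col), 0-based.
- Argmax ties break toward the lower class index (background first).
- Hot-spot component matching ties break toward the lower bone index.
- Pixels covered by no patch receive an "others"-wins logit vector.
- Empty-vs-empty Dice is defined as 1 so per-bone averages remain
  well-defined when a bone is absent from both rasters.
- "Cross-correlation" between measured and true BSI is the Pearson
  coefficient, the standard agreement statistic for BSI studies.
- Body-axis estimation needs an elongated mask; a near-isotropic mask
  (eigenvalue ratio > 0.98) is rejected as degenerate rather than guessed.
- Percentile-flat images (I10 = I98) are rejected in grey normalization.
- The label roundtrip standardize→invert preserves ≥ 99% of raster pixels;
  agreement restricted to labelled pixels is ~97–98% at desk raster sizes
  because several bones are only 2–3 px wide under the ~0.8× resample.

## Known limitations

- The shipped bone weight table is an approximate ICRP-style reference
  (the exact published per-bone fractions used clinically are not
  recoverable); every report records the table's provenance, and all
  correctness tests use synthetic tables.
- Desk-scale networks are orders of magnitude smaller than the clinical
  configuration; their absolute Dice/sensitivity values are not
  comparable to published clinical figures.
- Deep supervision is a gradient-flow aid for deep networks; at desk
  depth/width the skeleton network has no vanishing-gradient problem and
  the auxiliary heads instead divert capacity: in seeded desk-scale
  comparisons the DSV variant's output-layer Dice loss ends slightly
  *above* the naive variant's, so the suite's DSV-versus-naive training
  comparison fails at this scale and is reported as such rather than
  weakened. The benefit of deep supervision is a property of full-scale
  deep configurations.
- Alignment is translation-only after mirroring; rotational mismatch
  between views is not corrected (both views receive the same
  standardization rotation).
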