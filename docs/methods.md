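# Methods

## Problem

During oocyte micromanipulation (SCNT, ICSI, polar-body biopsy) the polar
body must be located so the cell can be rotated into position. Under a
brightfield microscope the polar body is only visible near the focal
plane, and cell rotation produces three failure modes for classical
detectors: defocus blur, deformation from micropipette contact, and large
variation in polar-body size between oocytes. `polarseg` treats detection
as semantic segmentation: a convolutional encoder-decoder predicts a
per-pixel polar-body probability, and a region-level non-maximum
suppression converts the map into a presence decision plus a centroid.

## Segmentation network

The network is a U-net-style contraction-expansion stack of nine
inception modules. Each module runs four parallel branches over its
input — (a) a 1x1 convolution, (b) 1x1 then 3x3, (c) 1x1 then the
factorised 1x3 and 3x1 pair, (d) a 3x3 same-padded max-pool followed by a
1x1 convolution — and concatenates the branch outputs along channels. The
1x1 convolutions reduce channel dimension while preserving spatial size;
the mixture of kernel shapes gives each module receptive fields at
several scales, which matters because polar bodies span roughly 4–16 px
in semi-axis at the nominal 16 px / 10 µm magnification.

Modules I1–I4 form the encoder, each followed by a 2x2 max-pool; I5 is
the bottleneck; I6–I9 form the decoder, each preceded by a 2x
up-convolution (stride-2 transposed convolution by default;
nearest-upsample + 3x3 convolution available as `up_mode="upsample"`) and
a channel concatenation with the symmetric encoder output (skip
connection). A 1x1 convolution and sigmoid produce the probability map,
so output size equals input size for any input whose sides are divisible
by 16.

Channel widths follow the standard U-net schedule — `base_channels` at
I1, doubling per encoder level, halving back through the decoder — split
equally across the four branches of each module. Every convolution is
followed by batch normalisation and a ReLU. Weights are He-uniform,
seeded. The head bias is initialised to the logit of `head_prior` (default
0.01), the approximate fraction of frame area a polar body occupies:
starting the output sigmoid near the foreground prior instead of at 0.5
removes the early epochs otherwise spent suppressing the background,
which matters at the short training budgets this package targets.

The layers, backpropagation and the Adam optimiser are implemented
directly on numpy arrays (NHWC layout, im2col convolutions, numba kernels
for patch extraction and pooling); training and inference run on a single
CPU core.

## Loss

Training minimises `dice + beta * bce` with `beta = 0.5`:

* **Soft Dice** `1 - (|P∩T| + eps) / (|P∪T| + eps)` with the product/sum
  relaxation (`|P∩T| = Σ p·t`, `|P∪T| = Σp + Σt − Σp·t`) and
  `eps = 1e-6`, computed per image and averaged over the batch. The
  epsilon makes an empty prediction on an empty target score 0, so
  correctly rejected negative samples are not penalised.
* **Pixel-wise binary cross-entropy**, mean over all pixels, predictions
  clipped to `[1e-7, 1 - 1e-7]`. Dice alone is indifferent to calibration
  far from the mask outline; the pixel term keeps the map sharp.

Both gradients are analytic and verified against central differences in
the test suite.

## Data augmentation

Three paired image/mask transforms emulate the ways a rotating oocyte
presents itself, and expand a dataset fourfold (original + one of each):

* **Rotation** by a uniform angle in [-90, 90] degrees about the canvas
  centre (in-plane rotation); bilinear for the image with border-median
  fill, nearest-neighbour + re-binarisation for the mask.
* **Axis flipping** (rotation out of the focal plane); exact index
  reversal for both.
* **Elastic deformation** (micropipette-induced squeezing): per-pixel
  displacements drawn i.i.d. uniform on (-1, 1), smoothed with a unit-sum
  Gaussian kernel of std `sigma` (truncated at 4 sigma), normalised to
  unit peak, and scaled by `alpha`; the image is resampled at
  `(r + dy, c + dx)` with reflect padding, the mask with the same field.
  The peak normalisation makes `alpha` the peak displacement in pixels
  regardless of `sigma` — without it, unit-sum smoothing shrinks the
  field's amplitude by roughly `1/sigma` and single-digit `alpha` values
  produce sub-pixel, effectively invisible warps. Defaults
  `alpha ∈ [6, 12]` px, `sigma ∈ [8, 12]` px keep the polar body
  connected while visibly deforming cell and organelle.

## Detection

The probability map is thresholded at `support_threshold` (default 0.1)
and 8-connected components are extracted. A component survives only if
its maximum probability reaches `prob_threshold` (default 0.5) and its
area reaches `min_area` pixels. Among survivors, the highest-maximum
region wins, ties broken by larger area and then by topmost-leftmost
centroid; the polar-body position is the mean of the winning region's
pixel coordinates. No survivor means "no polar body". Forming components
below 0.5 keeps the max-value constraint and the area constraint
independent: a broad, weakly confident blob is judged on its peak, not
dismembered at the acceptance threshold.

`min_area` defaults to 50 px on a 256x256 frame (the smallest plausible
polar body at 16 px / 10 µm comfortably exceeds it) and to 30 px in the
128x128 pipeline configuration.

## Evaluation

A detection on a positive image is correct when its centroid lies
strictly within 10 px (Euclidean; Chebyshev available) of the mask
centroid; on a negative image "absent" is the only correct answer.
Accuracy is reported overall and per class, with per-sample records
(distances, confidences, areas) retained for failure analysis.

## Synthetic scenes

No public dataset of annotated oocyte micrographs exists, so the package
generates its own: a textured cytoplasm disc inside a brighter zona
pellucida ring, holding/injection pipette bars touching the cell edge,
brightness varying per scene, Gaussian pixel noise, and — for positives —
a dark elliptical polar body with a bright rim centred in the gap between
cytoplasm and zona (radius `cell_radius − zona_thickness/2`). The mask is
the exact ellipse rasterisation. Three difficulty axes mirror cell
rotation:

* **defocused** — the polar body's contribution to the image is convolved
  with a Gaussian PSF, std drawn from [2, 6] px (the mask is unchanged:
  defocus moves the object out of the focal plane, not out of the scene);
* **deformed** — an elastic warp (`alpha ∈ [4, 10]` px) applied jointly to
  image and mask;
* **mixed** — each effect switched on independently with probability 1/2.

Polar-body semi-axes are drawn from [4, 16] px in all modes (clipped to
`cell_radius/3`), matching the size variation the 16 px / 10 µm scale
implies. Cytoplasm texture is low-frequency multiplicative noise, strong
enough that plain intensity thresholding cannot isolate the polar body.

What the generator does *not* model: real optics (diffraction, DIC-like
shading), z-stack consistency, debris, multi-cell fields, and the
texture statistics of real cytoplasm. Passing the end-to-end test shows
the learning and detection machinery works on scenes with the stated
geometry and difficulty axes; it is not evidence about accuracy on real
micrographs. A consequence of the defocus model worth knowing: a small
polar body blurred at the top of the PSF range spreads its contrast below
the noise floor and becomes genuinely invisible, so a few percent of
"defocused" positives are undetectable in principle; these dominate the
residual error of the end-to-end experiment.

## Training procedure and problem sizes

Adam (lr 2e-3, cosine-annealed to 0 over the run), batch size 4, a seeded
80/20 train/validation split, and best-validation-loss checkpointing. The
learning rate and schedule were chosen so that training converges within
the scaled-down budget below; at 1e-3 constant the loss is still falling
steeply when the budget ends.

The reference experiment (also what `scripts/acceptance.py` runs)
generates 400 training and 100 held-out scenes at 128x128 (mixed
difficulty, 25% negatives), trains 15 epochs with `base_channels = 16`
(~370k parameters), and evaluates with the 10-px criterion — minutes-scale
on one CPU core. These sizes are the package's scaled-down stand-in for a
full study (the method itself is size-agnostic; 256x256 scenes and wider
networks only cost time).

## Numerical and design notes

* Coordinates are (row, col), 0-based, row 0 at top, everywhere.
* Masks are stored as 8-bit PNG, 0/255; probability maps live in memory.
* Rotation snaps quarter-turn trigonometry to exact 0/±1 so 90-degree
  rotations are pure index permutations.
* All randomness flows from explicit integer seeds; the pipeline derives
  per-stage seeds from one global seed via `SeedSequence`. Reruns with the
  same configuration are bit-identical on the same platform.
* Batch-norm uses batch statistics in training and running statistics
  (momentum 0.9) at inference.
* Degenerate inputs: empty manifests, empty regions, non-divisible image
  sizes and out-of-range parameters raise `ValueError` with the offending
  quantity named; a non-finite loss aborts training naming epoch and batch.

## Known limitations

* The nine-module architecture is fixed; only width and the upsampling
  mode are configurable.
* Top-1 detection only: scenes with two polar bodies report the most
  confident one.
* CPU-only; no attempt at real-time throughput.
* Accuracy numbers from the synthetic experiment do not transfer to real
  microscope data without retraining and re-validation.
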