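# Methods

`barkcam` implements a pipeline for identifying tree species from trunk bark
photographs and for explaining the classifier's decisions with whole-image
saliency maps. This note records the models, the parameters that matter, and
the design choices made where the procedure was genuinely open.

## Pre-processing

Bark photographs are assumed side-cropped so that only fully-masked (all-black)
columns flank the trunk; `trim_masked_sides` removes exactly those columns. A
pixel is *masked* iff all three channels are exactly 0 — bark pixels that are
legitimately black are indistinguishable from mask, an accepted limitation
(the synthetic generator therefore never emits all-zero bark pixels).

Training patches are square crops whose side is drawn uniformly from
`frac_min`–`frac_max` of the image **width** (defaults 0.40–0.60). Because the
fraction is defined on the width but the crop must also fit the height, the
side is clamped to `min(H, W)`; portrait trunk photographs, the intended
input, are unaffected. A candidate crop is rejected and re-drawn whenever its
masked-pixel fraction exceeds the threshold tau = 0.05; after `max_attempts`
(default 100) rejections a `SamplingExhaustedError` names the offending image.
An unbounded retry loop would hang on heavily-masked inputs, hence the cap.

Test patches are a deterministic tiling: side = 0.50 of the width, stride =
side, origin (0, 0), row-major, partial tiles dropped, tiles over tau dropped.
The tiling origin and stride are a design choice — only the absence of
randomization is inherent to the protocol — and are documented here so crop
counts are reproducible. Evaluation is per cropped test sample, not per
photograph.

All geometry is 0-based with half-open extents. Resizing (and CAM
upsampling) uses **corner-aligned bilinear interpolation**: the output grid's
first/last samples coincide with the input's first/last pixels, so corner
values are preserved exactly, constant inputs stay constant, and resizing to
the native resolution is the identity. This convention is chosen over the
half-pixel convention because it makes small hand-checkable golden values
stable.

## Augmentation

A RandAugment-style scheme: `n_ops` (default 2) operations drawn uniformly
*with replacement* from {equalize, rotate, solarize, contrast, brightness,
color}, each applied at a magnitude uniform in `magnitude_range` (default
[0.1, 0.6]). Magnitude m maps to each operation's natural parameter: rotation
±30°·m (black corner fill, consistent with mask semantics), solarize threshold
255·(1−m), enhancement factor 1±m for contrast/brightness/color; equalize is
magnitude-free per-channel histogram equalization. The op list and both
hyper-parameters are config-exposed because the upstream protocol fixes only
the candidate families, not the numbers. Augmentation may recolor masked
pixels (equalize, rotation resampling); this is accepted because augmentation
runs only on crops that already passed the ≤5 % mask test.

## Classifier and training

The classification head follows standard transfer-learning surgery: feature
stack → flatten → dropout (rate 0.5) → fully-connected layer sized to the
label set → softmax with cross-entropy. `adapt_head` applies this to any
backbone exposing a convolutional feature stage.

At desk scale the backbone is a small from-scratch network written directly in
numpy (im2col convolutions, explicit backward passes, Adam): three 3×3
convolution blocks (16, 32, 64 channels; 2×2 max-pool after the first two),
with the output of the last ReLU as the **target layer** for saliency, then a
global-average-pool → dropout → dense head (the EfficientNet head shape).
Input resolution is 32 px. Two architecture choices matter for saliency
quality and were settled empirically. First, the head is *linear* on the
pooled features: with a hidden nonlinear layer the optimizer is free to score
a class through negative evidence ("no dark motifs present"), in which case
the positively-weighted feature maps — the only ones Grad-CAM++ can show,
since feature-map weights pass through relu(G) — fire on generic bark texture
and the saliency map anti-localizes on exactly one class while accuracy stays
high. Second, the last block is 64 maps wide: with 32 maps, whether a
dedicated positive feature for the lowest-contrast motif class emerges was
initialization-dependent, and runs without one showed the same per-class
saliency collapse. Writing the network by hand keeps the whole pipeline
dependency-light and, more importantly, gives exact analytic access to
dS_c/dA at the target layer; the probe's gradients are verified against
central finite differences in the test suite (relative error < 1e-3,
typically ~1e-10).

Training follows the full-scale protocol where the protocol fixes values:
Adam, batch size 8, dropout 0.5, early stopping when held-out overall accuracy
has not improved for 10 consecutive epochs, best-epoch weights restored. The
full-scale learning rate of 1e-5 presumes an ImageNet-pretrained backbone
being fine-tuned; training the small network from scratch uses 1e-3. One
"epoch" of the desk study is 160 batches streamed from the crop sampler
(crops and augmentation are generated concurrently with training, never
materialized). Note the protocol monitors early stopping on the *test* set —
it conflates test and validation; we reproduce that protocol in the reference
study but flag it here. Training is reproducible for a fixed seed under
single-threaded numpy; BLAS threading can introduce tiny nondeterminism.

## Grad-CAM++

For a class c with pre-softmax score S_c, the target-layer activations A^k and
gradient G^k = ∂S_c/∂A^k give the map

  α^k_ij = (G^k_ij)² / (2 (G^k_ij)² + Σ_ab A^k_ab (G^k_ij)³),  α = 0 where the
  denominator is 0 (standard practice for the degenerate cells);
  w_k = Σ_ij α^k_ij · relu(G^k_ij);  L_ij = relu(Σ_k w_k A^k_ij).

The exponential re-scoring Y_c = exp(S_c) is what reduces all higher
derivatives to powers of G; the common exp(S_c) prefactor cancels inside α
and is omitted. `compute_cam` performs **no per-window normalization**:
windows are later averaged into one map, and normalizing first would destroy
their relative scale. Min–max normalization happens once, at render time.

## Whole-image aggregation

The image is padded with black pixels: one stride on top/left, and on
bottom/right one stride plus the remainder making (dim + padding − window)
divisible by the stride, so the sliding grid tiles exactly. The window side
defaults to 0.50 of the image width (matching the deterministic test-crop
fraction; the aggregation window size is not otherwise pinned down), the
stride is fixed at half the window. Each window is resized to the model
input, probed, its Grad-CAM++ map upsampled back to window size and added
into an accumulator; the final map divides by the *actual* per-pixel coverage
count and crops back to the original frame. Dividing by true coverage (rather
than assuming uniform overlap) makes the output an exact per-pixel mean — the
test suite checks equality with a brute-force per-pixel oracle to 1e-9.
Aggregation is linear in the per-window maps, and a constant per-window map
yields an exactly constant saliency map.

The explained class defaults to the majority argmax prediction across windows
and is logged; explaining the true label instead is supported by passing
`class_index` (which of the two the original protocol used is not stated, so
neither is presumed).

## Evaluation metrics

Sokolova–Lapalme multiclass measures with overall accuracy in place of
average accuracy: overall accuracy = Σ_i tp_i / (tp_i+tn_i+fp_i+fn_i) =
trace/N; macro precision/recall are unweighted means of per-class ratios; the
F-score is the harmonic mean (β = 1) of the **macro averages** — not the mean
of per-class F1, which is what most libraries compute, hence the hand-rolled
implementation. A class with a zero denominator contributes 0 to the macro
mean (Sokolova–Lapalme convention; with 42 well-populated classes this never
triggers on real data). When mirroring printed tables, percentages round to
1 decimal and F-scores to 2.

Higher-taxon rates score predictions of species absent from training: the
fraction of samples whose predicted species shares the true species' genus
(resp. family), given a species→genus→family table. With nested taxonomies
the genus rate cannot exceed the family rate.

## Synthetic data

The generator emulates the structure that makes bark identifiable: a
correlated-noise base texture (Gaussian noise, σ = 12 intensity, smoothed at
σ = 1.2 px, around a common brown base color) **identical across classes**,
with class-specific motifs drawn on top — bright elliptical blisters, dark
horizontally-elongated lenticels, full-height bright vertical stripes, dark
meandering vertical fissures, dark scale outlines, or nothing (smooth). Motif
count is ⌈density·50⌉ (default density 0.12). Because the base texture carries
no class signal, a classifier must attend to motif pixels, making the exact
motif mask a quantitative ground truth for saliency localization — something
the real datasets, reviewed qualitatively, cannot provide.

Images are 96 px with 10 %-of-width black side margins whose inner boundary is
a ±2 px ragged random walk, emulating the non-vertical trunk edge left after
side-cropping; this keeps residual masked wedges near the rejection threshold
so the tau path is genuinely exercised without starving the deterministic
tiling. Moss-like green blobs appear with probability 0.3 per image as
nuisance content, disjoint from the motif mask. Bark pixels are clipped to
≥ 1 so none is accidentally "masked".

What the generator does **not** model: photorealistic bark, intraspecific
variation with age and environment, lighting/scale variation between
photographs, and the visual diversity of real backgrounds. Passing desk-scale
tests therefore demonstrates that the pipeline's machinery is correct and
that saliency concentrates on class-defining texture when one exists — not
that any particular accuracy transfers to real species.

## Reference study conditions

Four motif classes (blisters, horizontal lenticels, vertical stripes,
fissures), 200 images per class, stratified 80/20 train/test split, per-crop
evaluation (~2 test crops per image), 32 px patches, training as above. All
randomness fans out from one root seed through named `SeedSequence` children
(data, stream, init, train), so subsystems are independently reproducible.

## Known limitations

- The probe differentiates the pre-softmax score; backbones whose feature
  stack ends in something other than a spatial activation map are unsupported.
- 2×2 max-pool gradients split evenly across exact ties (irrelevant for
  generic float activations, and pooling never sits between the target layer
  and the head).
- `mask_ratio` treats true-black bark as background; real pipelines should
  supply an explicit mask raster where this matters.
- The numpy backbone is desk-scale by design; it is not a path to training on
  full-resolution photograph collections.
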