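# Methods

## Problem setting

Colposcopy-guided diagnosis of cervical intraepithelial neoplasia (CIN)
hinges on delineating acetowhite epithelium — tissue that whitens after
acetic acid application. The toolkit treats this as binary semantic
segmentation: each pixel of an RGB colposcopy frame is classified lesion /
background. Expert annotations arrive as labeled polygons (LabelMe dialect);
the clinical grade (CIN1/2/3) accompanies each image and is used for
stratification, not as a prediction target.

## Annotation rasterization

Masks are produced from polygons with an explicit, testable inclusion rule:
vertices are rounded to the integer grid, and a pixel belongs to the mask
iff its center lies inside the polygon under the even-odd rule or exactly on
an edge. Multiple shapes merge by union (overlapping lesion outlines do not
cancel). Out-of-frame vertices need no special clipping: only in-frame pixel
centers are tested, which is equivalent to clipping the polygon to the frame
first. Polygons with zero shoelace area contribute nothing and are logged.
The rule is verified against an independent geometric oracle (shapely
`covers` on pixel centers) in the test suite; the two agree exactly on
random simple polygons, in and out of frame.

## Data pipeline

Images and masks are resized to a square input (default 256), images
bilinearly with intensities scaled to [0, 1], masks by nearest neighbor and
re-thresholded at 0.5 so no interpolation gray values survive. Each encoder
branch standardizes its input with the constants conventional for its
family: natural-image channel statistics (mean 123.675/116.28/103.53, std
58.395/57.12/57.375 on the 0–255 scale) for the resnet-style branch, and
symmetric ±1 scaling (127.5/127.5) for the mobilenet-style branch.

Augmentation draws from four transform families — rotations, flips,
brightness/contrast shifts, elastic deformations — with the same geometric
transform applied to image and mask (photometric changes touch the image
only). Defaults: rotation ±30°, both flips at p = 0.5, brightness/contrast
±0.2, elastic α = 40 px / σ = 6 px; all configurable. Elastic fields are
gaussian-filtered uniform displacement maps applied with nearest-neighbor
resampling on the mask.

Offline expansion grows a dataset to a target size while preserving class
proportions. Per-class targets use largest-remainder rounding, which is the
only standard rule guaranteeing the expanded counts sum exactly to the
target; each class lands within one sample of its exact proportional share.
Originals are always retained and augmented copies carry provenance ids.
Splitting is stratified 8:1:1 by default, deterministic per seed, with
largest-remainder allocation inside each class.

The class-imbalance statistic is 100·(max − min)/total over class counts —
the spread between the largest and smallest class share. For a 278/286/296
cohort this is 2.09%.

## Network

Design constraints, in order: honor the published tensor contract at every
named intermediate (tap channels 64/128/256/512 and 16/24/32/96 at strides
2/4/8/16, fused 608×16×16, context block 1024×16×16, decoder
512/256/128/64, output 1×H×W); keep every architectural idea — dual
encoders, SE-gated skips, lightweight ASPP, transposed-convolution decoder —
structurally faithful; and stay trainable on one CPU.

The encoders are compact in-package implementations of their families:
bottleneck residual stages (1×1 reduce → 3×3 → 1×1 expand, projection
shortcut on shape change) for the resnet-style branch, inverted residual
stages (1×1 expand → depthwise 3×3 → linear 1×1 project) for the
mobilenet-style branch. Internal stage widths are configuration knobs; 1×1
projection convolutions at each tap pin the published channel contract
regardless of internal width, so the contract tests are width-independent.
Only random initialization is provided — the package runs fully offline, so
no pretrained weights are downloaded; `pretrained_backbones=True` is
rejected explicitly rather than silently ignored.

Fusion concatenates per-level taps after bilinearly resizing the
mobilenet-style map to the resnet-style map's grid (a no-op when both
branches share the input, kept for robustness). SE gating sits on each skip
connection after fusion and before decoder concatenation (reduction 16 by
default; the bottleneck rounds up to at least one unit). The ASPP block uses
depthwise-separable 3×3 branches at dilations 1/6/12 plus a global-pool
branch broadcast back to the grid; with 256-channel branches its output is
the 1024-channel map the contract prints, so the 608 → 1024 transformation
is realized by ASPP itself.

The decoder has four stages of kernel-2 stride-2 transposed convolution
followed by two 3×3 conv+BN+ReLU refinements. Stages 1–3 concatenate the
SE-gated fused skips at strides 8/4/2. Stage 4 has no skip: with four taps
at strides 2–16 and the deepest level consumed by ASPP, there is no stride-1
feature map left to fuse, so the last stage upsamples and refines only. The
head is a 1×1 convolution with sigmoid; predictions binarize at 0.5 (the
threshold is a parameter; no published value exists).

The ablation variant removes the mobilenet-style branch: skips are SE-gated
resnet taps and the ASPP input is the deepest resnet tap (512 channels at
default width). It is strictly a submodel, so its parameter count is lower
than the full model's at identical widths; parameter counts are logged at
build time but not asserted against any external figure.

## Autodiff engine

`cervseg.nn` is a minimal reverse-mode automatic-differentiation engine on
numpy arrays: tensors record their producing operation, and a topological
backward pass accumulates gradients. Convolutions use im2col with matmul;
transposed convolution is implemented directly for the kernel-2/stride-2
case; bilinear resizing is a pair of interpolation-matrix contractions
(half-pixel centers, row-stochastic, hence constant-preserving); batch
normalization keeps running statistics with momentum 0.1 and uses the full
train-mode gradient. Parameters are float32, He-initialized from a seeded
generator so two builds with the same seed are bit-identical. Every operator
is validated against scipy forward oracles and central-difference gradients
in the test suite. An `Adam` optimizer (β = 0.9/0.999, ε = 1e−8) completes
the training stack.

## Losses

Dice and Tversky losses follow their standard smoothed forms with a shared
ε = 1e−6; the training objective is their sum. Sums run over all pixels of
the batch rather than per image — the simplest reading of the defining sums,
and more stable when single images contain tiny lesions. α = 0.7 / β = 0.3
by default (false negatives cost more, appropriate for small lesions); at
α = β = 0.5 the Tversky loss reduces exactly to Dice in the ε → 0 limit,
which the tests verify numerically. An optional binary cross-entropy term
exists behind a flag and defaults off: the governing definition of the
combined loss is Dice + Tversky.

## Metrics

PA, MPA, MIoU, FW-IoU and Dice derive from a pooled 2×2 pixel confusion
matrix accumulated over the evaluation set (pooling matches how published
comparison tables are conventionally computed); Hausdorff distance and
Cohen's κ average per image. Boundaries for the Hausdorff distance are
foreground pixels with a background 4-neighbor or on the image edge; the
distance is the symmetric max of directed sup-inf Euclidean distances
(scipy's directed Hausdorff on both orderings). When either mask has empty
foreground the distance is undefined: such pairs are excluded from the
average and counted in the report, never silently scored as zero. MPA
excludes classes absent from the ground truth with a logged warning. κ for
two constant, identical raters is defined as 1; constant-but-different
raters raise.

## Grad-CAM++

For dense sigmoid outputs the "class score" is taken as the sum of predicted
probabilities over pixels the model calls foreground (p > 0.5). Channel
weights follow the Grad-CAM++ form: α = g²/(2g² + Σ A g³) per spatial
position (guarded where the denominator vanishes), weighted by ReLU of the
gradient and summed spatially. The weighted channel sum is ReLU'd, min-max
normalized (idempotent; all-zero maps stay zero, with a warning when the
gradient field is identically zero), and bilinearly upsampled to the input
size. The default layer is the deepest resnet-branch tap. Heatmap/mask
agreement uses κ after binarizing the heatmap at 0.5 (configurable; no
published threshold exists).

## Phantom generator

Phantoms emulate the structure of a graded colposcopy dataset, not its
appearance: a dark frame; a bright pinkish ellipse covering 40–70% of the
frame (the cervix field); lesion blobs as radial-harmonic polygons
r(θ) = R(1 + Σ_{h=2..5} a_h sin(hθ + φ_h)), |a_h| ≤ 0.25/(h−1), sampled at
72 vertices, placed with all vertices inside the ellipse (convexity of the
ellipse then contains the whole polygon); lesion brightness raised by a
contrast delta (default 0.30) to mimic acetowhitening; Gaussian texture
noise (σ = 0.03); and small saturated discs inside the field but never
touching the mask, mimicking specular highlights a good model must ignore.
Per-class lesion area fractions — CIN1 (0.02, 0.06), CIN2 (0.06, 0.12),
CIN3 (0.12, 0.22) — are invented morphometry chosen to give a learnable
grade-correlated signal and small-lesion class-imbalance pressure; the
generator measures the rasterized union and redraws until the fraction lands
in range. Masks ship alongside the generating polygons as LabelMe-dialect
annotations, and re-rasterizing those annotations reproduces the shipped
masks exactly.

What phantoms do not model: real acetowhite texture, vasculature, green
filter or iodine modalities, occlusions, and inter-annotator variability.
Passing the phantom benchmarks therefore demonstrates that the pipeline,
architecture, losses and metrics are implemented correctly and can learn a
lesion-like signal under artifacts — not clinical-grade performance.

## Training recipes and problem sizes

The configuration default mirrors the published strategy: 256×256 inputs,
Adam at 1e−4, batch 16, up to 300 epochs, early stopping (patience 25) and
reduce-on-plateau (×0.5, patience 10; both mechanisms are named in the
source strategy without parameters — these are conventional values), with
online augmentation enabled. Checkpointing keeps the weights with the best
validation combined loss.

The desk-scale recipe — the size this package trains at in its own test
suite — uses 64×64 phantoms (150 train / 30 val / 30 test), a narrow model
(taps 8/12/16/24 and 4/6/8/12, ASPP branches of 16, decoder 24/16/12/8,
single block per stage), 30 epochs, batch 8, Adam at 3e−3, and mild online
augmentation (±15° rotation, flips, ±0.1 brightness/contrast, no elastic).
It reaches held-out Dice ≈ 0.98 in a few minutes on one CPU; the acceptance
suite requires ≥ 0.80 in at least two of three fixed seeds.

## Numerical and degenerate-input choices

- Mask values are validated to {0, 1} at container boundaries; resized
  masks re-binarize before use.
- The SE bottleneck width is ⌈C/reduction⌉, never below 1.
- ASPP pads dilated branches to preserve spatial size even when the grid is
  smaller than a branch's receptive field.
- Evaluation with a threshold ≥ 1 produces empty predictions; region
  metrics still pool, the Hausdorff distance is reported as missing.
- NaN/Inf training loss aborts with the current learning rate and batch
  statistics in the message rather than continuing silently.
- Loss ε defaults to 1e−6; the Dice/Tversky reduction identity is asserted
  at ε = 1e−12 where the finite-ε bias is below the comparison tolerance.

## Known limitations

- No pretrained encoder weights; transfer-learning results are out of reach
  offline, and headline clinical accuracies require the private cohort.
- The engine is CPU-bound numpy: full-size (256×256) training is possible
  but slow; the desk recipe is the supported training size for CI-like
  environments.
- Binary masks only; the CIN grade conditions generation and stratification
  but is not predicted.
- Per-image Euclidean Hausdorff distances on 256² images are bounded by the
  image diagonal (≈ 362 px); published tables reporting four-digit pixel
  distances use an unstated aggregation that cannot be reconstructed, so no
  comparison against them is attempted.
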