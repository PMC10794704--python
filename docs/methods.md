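# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package, in the order the pipeline runs.

## Synthetic phantoms

The phantom generator emulates the statistical structure the
brain-extraction stage assumes about axial MRI slices: a bright brain
region on a dark, mildly noisy background. Each phantom is an
axis-aligned ellipse (semi-axes uniform in 0.30–0.42 of the image side,
center jittered ±4%) of mean intensity 140 on a background of 8, with
additive Gaussian noise (σ = 6 gray levels) and clipping to [0, 255].
Class-conditional lesions, drawn strictly inside a margin-eroded ellipse:

| class      | lesion                                                          |
|------------|-----------------------------------------------------------------|
| glioma     | union of 3–5 circular lobes (r = 6–12 px), smoothed heterogeneous intensity field in 90–220 |
| meningioma | one circle (r = 8–14 px), uniform intensity 200                  |
| pituitary  | small circle (r = 4–8 px) in the lower-middle fifth of the ellipse, intensity 210 |
| notumor    | none                                                             |

Lengths are defined at a 128-px reference resolution and scale linearly
with `image_size`. Three bright distractor specks (r = 2–6 px, area ≪
1000) are scattered on the background so the contour-area filter is
actually exercised rather than dead code. The classes are deliberately
separable by lesion morphology (size, intensity, texture, position) so a
scaled-down classifier has a learnable signal.

What the phantoms do **not** model: bias fields, k-space/motion
artifacts, anatomy (ventricles, skull, gyri), 3-D continuity, intensity
non-uniformity within healthy tissue, or inter-scanner variation.
Passing tests on phantoms therefore demonstrates that the pipeline's
machinery (extraction, training, metrics, explanations) is correct and
deterministic — not that the classifier reaches any particular accuracy
on clinical MRI.

## Brain extraction

Order of operations: standardize (decode, luminance gray, bilinear resize
to `target_size`, default 128) → Gaussian blur on a working copy →
Otsu threshold → connected-component area filter → filled-mask overlay →
crop → power-law transform → final resize.

Numerical choices:

* **Blur.** Explicit n×n kernel (default n = 11) from the bivariate
  Gaussian with σ = (n−1)/6, normalized to unit sum; borders replicate
  edges. The blurred copy only drives the threshold; the mask and crop
  are applied to the *un-blurred* standardized image so the classifier
  sees full detail.
* **Otsu.** Histogram formulation with classes `≤ T` / `> T`; the score
  ω₁ω₂(μ₁−μ₂)² is evaluated for every T with both classes non-empty and
  the lowest maximizing T wins ties. A constant image has no valid split
  and sets a degenerate flag; the pipeline falls back to a full-image
  region of interest and logs a warning. Foreground is the bright side
  by default (`foreground_bright` config flag for inverted inputs).
* **Contour area.** "Contour" is an 8-connected foreground component and
  its area is the *filled* pixel count (holes included). The default
  minimum area 1000 is interpreted at the 128-px working resolution and
  scales quadratically for other sizes (exposed in config). Among
  qualifying components the largest wins; equal areas tie-break to the
  component whose first pixel comes first in row-major order (scipy's
  raster-scan labeling order), for determinism.
* **Power law.** Q = pixel/255, P = clip(k·Q^β, 0, 1), output
  round(P·255). β defaults to 1.5; the gain k defaults to 1 because on
  [0, 1]-normalized values any other constant merely rescales or clips.
* **Final resize.** Crops vary in size, so the cropped, transformed image
  is bilinearly resized back to `target_size` — the network input shape
  is fixed. Aspect ratio is not preserved anywhere (the usual
  fixed-input-CNN convention).

## Augmentation

Rotation (uniform 0–25°, as printed; a symmetric ±25° option is
config-gated), shear (0–0.2), zoom (1–1.2 per axis), width/height shift
(±0.2 of the dimension), horizontal flip (Bernoulli 0.5). The four
continuous operators compose into a single affine warp about the image
center — one bilinear resampling pass avoids compounding interpolation
blur — in a configurable order (rotate→shear→zoom→shift by default); the
flip is applied afterwards as an exact mirror so a double flip is
bit-identical. Out-of-frame samples replicate the nearest edge, avoiding
synthetic black borders that contour-sensitive features would latch onto.
Augmentation applies to the training stream only; the harness records
which dataset indices passed through it so the contract is assertable.

## Network

The backbone is the VGG19 feature stack — five blocks of 2/2/4/4/4
stride-1 3×3 convolutions with ReLU, each followed by a 2×2 max-pool —
truncated after the fifth pool; the three fully-connected layers are
discarded because only a spatial map can feed the pooling levels that
follow. A 128×128 input yields 4×4×512.

Each iPPM level nearest-upsamples by s, max-pools with window/stride s,
and applies a 1×1 convolution (128 filters per level by default; the
filter count is not prescribed anywhere, and 4×128 keeps the
concatenation at the backbone's width). Because the pooling windows
align exactly with the s×s blocks of repeated pixels, the
upsample-then-pool composition is the *identity map*, and each level is
numerically a 1×1 convolution of its input. The stages are implemented
literally as specified and the identity is asserted in tests; an optional
identity branch in the concatenation is config-gated but off by default
(the concatenation is defined over the pyramid levels only).

Head: 3×3 conv (256) → ReLU → 3×3 conv (128) → ReLU → global average
pooling → dense softmax over 4 classes. Embeddings for downstream
projection are the global-average-pooled vectors.

The conv/pool/upsample primitives, reverse-mode gradients and the Adam
optimizer are implemented in-package on numpy (NHWC layout, float32,
im2col convolutions, He-normal initialization seeded through
`numpy.random.Generator`), so identical seeds give bit-identical
parameters and training trajectories on any machine. Correctness is
established by hand-computed convolution cases and finite-difference
gradient checks over every layer type.

**Pretrained weights.** ImageNet-pretrained VGG19 weights are a named
external resource; requesting `pretrained_backbone=True` raises an
explicit error when they are not supplied. Random initialization is the
default and is what all tests use.

**Input scaling.** Network inputs are scaled to [−1, 1]
(pixel/127.5 − 1). With all-positive inputs, every first-layer weight
gradient shares the sign of its unit's error term, which measurably slows
early convergence; zero-centering removed a long plateau at the ln 4 loss
floor in the scaled-down runs.

**Tiny variant.** For CPU-scale verification a `ModelConfig.tiny()`
preset swaps the backbone for three single-conv blocks (16/32/64
channels) and narrows the iPPM (32 filters/level) and head (128/64),
keeping every architectural contract (backbone → iPPM → two 3×3 convs →
GAP → softmax). Two-block variants plateaued near chance within the
ten-epoch sanity budget; three blocks converge reliably. The sanity run
uses 400 phantoms (300 train / 100 validation), 10 epochs, batch 32, Adam
10⁻³ at 128×128 — about three minutes on one CPU.

## Training

Stratified k-fold cross-validation (default k = 3; stratification keeps
per-class proportions within one item per fold, which the per-class
metrics need). Defaults mirror the reference protocol: Adam
(lr 10⁻⁵, β₁ = 0.9, β₂ = 0.999), sparse categorical cross-entropy over
integer labels, batch 32, 50 epochs, no early stopping. The checkpoint
is overwritten only on strict validation-accuracy improvement, so ties
keep the earlier epoch. Fold i trains an independent model seeded
`base_seed + i`. A diverged run settles at the uniform-prediction loss
floor ln 4 ≈ 1.3863, which the suite asserts analytically.

## Metrics

All metrics are computed from the K×K confusion matrix via the
one-vs-rest reduction; accuracy is trace/total (the multi-class reduction
of the binary formula). Aggregates are unweighted macro means — the
printed aggregate in the reference results does not state its averaging,
and macro is neutral to class balance; a weighted variant is available.
Zero denominators define the metric as 0 with a warning. κ uses
p_o = trace/total and p_e = Σ row·col/total²; p_e = 1 raises (undefined).
The micro-averaged ROC flattens all N·K one-vs-rest (indicator, score)
pairs, sweeps the distinct scores as thresholds (score ≥ t positive), and
integrates trapezoidally. Argmax ties in prediction break to the lowest
class index. Implementations are verified against loop-based oracles, a
pair-counting AUC oracle (P(s⁺ > s⁻) + ½P(tie)), and scikit-learn.

## Explanations

One fixed, deterministic SLIC superpixel partition per image; run r
(r = 0..n_runs−1) draws Bernoulli(0.5) on/off masks with seed
`base_seed + r`, replaces switched-off superpixels by the image mean,
queries the model, and fits a ridge-regularized (α = 1) weighted linear
surrogate for the predicted class, with exponential kernel
exp(−d²/0.25²) on the cosine distance between the mask and the all-ones
mask. The explanation is the arithmetic mean of the 20 per-run
coefficient vectors (default n_runs = 20, n_samples = 3000 perturbations
per run). Keeping the segmentation fixed across runs is what makes the
per-run weights comparable elementwise; re-segmenting would make
averaging ill-defined. The granularity knob ("superpixel level") is
interpreted as the perturbation-sample count — a 3000-segment partition
of a 128×128 image would leave ~5 pixels per segment, too fine to be an
interpretable region — and both knobs are exposed in config. An
input-ignoring model yields exactly zero coefficients (a weighted ridge
fit to a constant target has zero slope), which the suite asserts.

## Problem sizes used in verification

Oracle comparisons run on 1000 random 16×16 images (threshold
selection), 1000 random confusion matrices, 200 random score sets (AUC),
and 100 random tensors (pooling identity). Preprocessing coverage is
measured on 200 phantoms; the training sanity check uses 400 phantoms for
10 epochs; the explanation protocol is verified with 20 runs of 100
perturbations on a 32×32 tiny model. These sizes were chosen so the
whole suite verifies the pipeline end-to-end on a single CPU in a few
minutes while keeping every check statistically meaningful.

## Known limitations

* Phantom realism as above; no claim transfers to clinical data without
  the real dataset and full-scale training.
* The full VGG19 variant is buildable and runs forward/backward, but
  training it at scale on numpy is impractical; the tiny variant carries
  the training-path verification.
* No pretrained weights are bundled, so the pretrained configuration is
  only exercised through its error contract.
* Micro-averaged ROC only (no per-class curves); no calibration analysis.
* 2-D slices only — no DICOM/NIfTI volume handling.
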