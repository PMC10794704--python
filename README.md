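# neuronet19

Brain-tumor MRI classification for four classes — glioma, meningioma,
pituitary tumor, and no tumor — built around three pieces:

1. **Deterministic brain extraction.** Each slice is resized to a fixed
   working resolution, blurred with an 11×11 Gaussian (σ = (n−1)/6),
   thresholded with Otsu's method (maximize ω₁ω₂(μ₁−μ₂)² over the gray
   histogram), reduced to its largest filled contour above a 1000-px area
   threshold, cropped to that contour's bounding box, and passed through a
   power-law transform P = k·Q^β (β = 1.5) that emphasizes bright
   structure.
2. **A VGG19 + inverted-pyramid-pooling classifier.** The 16-convolution
   VGG19 feature stack maps a 128×128 input to a 4×4×512 tensor. The
   inverted pyramid pooling module (iPPM) processes it at pool sizes
   s ∈ {2, 3, 4, 6}: nearest-neighbor upsample by s
   (U(i,j) = I(⌊i/s⌋, ⌊j/s⌋)), max-pool with window and stride s, apply a
   1×1 convolution (128 filters), and concatenate the levels channel-wise.
   Two 3×3 convolutions (256, 128 filters), global average pooling, and a
   softmax layer produce the four class probabilities.
3. **Evaluation and explanation.** One-vs-rest precision/recall/F1,
   accuracy, Cohen's κ = (p_o − p_e)/(1 − p_e), the micro-averaged ROC/AUC,
   and a stability-oriented LIME protocol: 20 repeated surrogate fits over
   one fixed superpixel segmentation, averaged into a single importance
   map.

Training uses stratified 3-fold cross-validation, Adam, sparse categorical
cross-entropy, batch size 32, and best-validation-accuracy checkpointing,
with affine augmentation (rotation 0–25°, horizontal flip, shear ≤ 0.2,
zoom ≤ 0.2, shifts ≤ 0.2) applied to the training stream only.

Because the real dataset is an external download and full training is
GPU-scale, the package ships a **synthetic phantom generator**: bright
elliptical "brains" on dark noisy backgrounds with class-conditional
lesions (irregular heterogeneous blob / uniform circle / small basal
circle / none) and sub-threshold distractor specks. Every stage of the
toolchain is testable on phantoms at desk scale; the convolutional engine
itself (NHWC conv/pool/upsample layers, reverse-mode gradients, Adam) is
implemented in-package on numpy.

Intended users: researchers reproducing or extending multi-scale-pooling
MRI classifiers, and anyone needing a fully deterministic, CPU-verifiable
reference implementation of this pipeline.

## Worked example

```python
import numpy as np
from neuronet19 import (PhantomSpec, generate_phantom, PreprocessConfig,
                        preprocess_pipeline, ModelConfig, build_neuronet19,
                        TrainConfig, AugmentConfig, train_fold, evaluate_model)
from neuronet19.phantoms import CLASS_NAMES

spec, pcfg = PhantomSpec(), PreprocessConfig()
imgs, labels = [], []
for i in range(100):
    for c in range(4):
        ph = generate_phantom(c, spec, seed=i)
        imgs.append(preprocess_pipeline(ph.pixels, pcfg))
        labels.append(c)
x, y = np.stack(imgs), np.array(labels)

perm = np.random.default_rng(0).permutation(400)
tr, va = perm[:300], perm[300:]
model = build_neuronet19(ModelConfig.tiny(input_size=128), seed=0)
cfg = TrainConfig(epochs=10, learning_rate=1e-3, batch_size=32,
                  base_seed=0, augment=AugmentConfig())
state, hist = train_fold(model, tr, va, x, y, cfg)
model.load_state_dict(state)
report, cm, roc = evaluate_model(model, x[va], y[va], list(CLASS_NAMES))
print(f"best val acc {max(hist.val_accuracy):.2f}  "
      f"kappa {report.kappa:.2f}  micro-AUC {roc.auc:.3f}")
```

This prints (deterministically, on any machine):

```
best val acc 0.96  kappa 0.95  micro-AUC 0.998
```

i.e. the tiny-backbone variant separates the four phantom classes at 96%
validation accuracy after ten epochs (chance is 25%), with
chance-corrected agreement κ = 0.95 and a micro-averaged AUC near 1 —
the signal the phantom classes are constructed to carry.

The same pipeline is scriptable from the shell:

```sh
nn19 phantoms --out data/train --n-per-class 100 --seed 0
nn19 run --data data/train --out runs --seed 0
nn19 explain --model runs/<run>/checkpoint_fold0.npz \
             --image data/train/glioma/0000.png --runs 20 --out overlay.png
```

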