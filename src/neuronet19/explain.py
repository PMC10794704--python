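"""Repeated-LIME explanations with a stability protocol.

LIME explains a single prediction by segmenting the image into
superpixels, randomly switching subsets of them off, querying the model on
each perturbed image, and fitting a locally weighted linear surrogate
whose coefficients rank superpixel importance.  Because a single run is
stochastic, the protocol here repeats the procedure ``n_runs`` times
(default 20) over one *fixed* segmentation — only the perturbation seed
varies per run — and reports the arithmetic mean of the per-run weights.
Holding the segmentation fixed is what makes per-run weights comparable
elementwise, which averaging requires.

Surrogate details follow conventional LIME defaults: Bernoulli(0.5)
on/off masks, switched-off superpixels replaced by the image mean, an
exponential kernel on the cosine distance between a mask and the all-ones
mask, and a ridge-regularized weighted linear fit for the predicted
class's probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import slic
from sklearn.linear_model import Ridge

__all__ = ["ExplainConfig", "Explanation", "segment_image", "explain_image",
           "render_overlay"]


@dataclass(frozen=True)
class ExplainConfig:
    """``n_samples`` is the number of perturbation samples per run (3000 by
    default); ``n_runs`` the number of repeated runs averaged (20).  The
    segmentation granularity is ``n_segments`` target superpixels for the
    deterministic SLIC partition."""

    n_runs: int = 20
    n_samples: int = 3000
    base_seed: int = 0
    n_segments: int = 50
    slic_compactness: float = 0.25
    kernel_width: float = 0.25
    ridge_alpha: float = 1.0
    batch_size: int = 256

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.n_segments < 2:
            raise ValueError("n_segments must be >= 2")


@dataclass
class Explanation:
    segment_map: np.ndarray          # (H, W) superpixel ids, contiguous from 0
    mean_weight: np.ndarray          # (n_segments,)
    per_run_weights: np.ndarray      # (n_runs, n_segments)
    predicted_class: int
    class_probs: np.ndarray

    @property
    def n_segments(self) -> int:
        return int(self.segment_map.max()) + 1


def segment_image(image: np.ndarray, config: ExplainConfig) -> np.ndarray:
    """Deterministic SLIC superpixel partition with contiguous ids from 0."""
    img = np.asarray(image, dtype=np.float64) / 255.0
    seg = slic(img, n_segments=config.n_segments,
               compactness=config.slic_compactness, channel_axis=None,
               start_label=0, enforce_connectivity=True)
    # relabel to contiguous 0..m-1 (SLIC may drop target labels)
    _, seg = np.unique(seg, return_inverse=True)
    return seg.reshape(np.asarray(image).shape[:2])


def _predict(model, batch: np.ndarray) -> np.ndarray:
    """Accept a Network, an object with predict_proba, or a plain callable."""
    from .model import prepare_batch

    fn = getattr(model, "predict_proba", model)
    return np.asarray(fn(prepare_batch(batch)))


def _run_weights(model, image, seg, m, target, config, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    baseline = float(np.asarray(image).mean())
    z = rng.integers(0, 2, size=(config.n_samples, m)).astype(np.float64)
    z[0] = 1.0  # anchor the neighborhood with the unperturbed image
    targets = np.empty(config.n_samples)
    for start in range(0, config.n_samples, config.batch_size):
        zz = z[start:start + config.batch_size]
        on = zz[:, seg.ravel()].reshape(len(zz), *seg.shape)
        batch = np.where(on > 0, image[None].astype(np.float64), baseline)
        probs = _predict(model, np.rint(batch).astype(np.uint8))
        targets[start:start + config.batch_size] = probs[:, target]
    # exponential kernel on cosine distance to the all-ones mask
    norm = np.sqrt(z.sum(axis=1)) * np.sqrt(m)
    cos = np.divide(z.sum(axis=1), norm, out=np.zeros_like(targets), where=norm > 0)
    dist = 1.0 - cos
    weights = np.exp(-(dist ** 2) / config.kernel_width ** 2)
    reg = Ridge(alpha=config.ridge_alpha, fit_intercept=True)
    reg.fit(z, targets, sample_weight=weights)
    return reg.coef_.copy()


def explain_image(model, image: np.ndarray,
                  config: ExplainConfig = ExplainConfig()) -> Explanation:
    """Mean-of-n-runs LIME explanation for one preprocessed gray image.

    Deterministic in ``(model, image, config)``: run ``r`` perturbs with
    seed ``base_seed + r`` over one fixed segmentation.
    """
    config.validate()
    image = np.asarray(image)
    probs = _predict(model, image[None])[0]
    target = int(np.argmax(probs))
    seg = segment_image(image, config)
    m = int(seg.max()) + 1
    per_run = np.stack([
        _run_weights(model, image, seg, m, target, config, config.base_seed + r)
        for r in range(config.n_runs)
    ])
    return Explanation(
        segment_map=seg,
        mean_weight=per_run.mean(axis=0),
        per_run_weights=per_run,
        predicted_class=target,
        class_probs=probs,
    )


def render_overlay(image: np.ndarray, expl: Explanation,
                   top_k: int = 5) -> np.ndarray:
    """Tint the top-k superpixels by |mean weight| over the gray image.

    Positive-weight segments (supporting the predicted class) are tinted
    green, negative red; a two-swatch legend sits in the bottom-left
    corner.  Output is an RGB uint8 image of the input's dimensions.
    """
    img = np.asarray(image)
    if img.shape[:2] != expl.segment_map.shape:
        raise ValueError("image and explanation shapes differ")
    m = expl.n_segments
    if top_k > m:
        import logging
        logging.getLogger(__name__).warning(
            "top_k=%d exceeds %d segments; clamping", top_k, m)
        top_k = m
    rgb = np.repeat(img.astype(np.float64)[..., None], 3, axis=2)
    if top_k > 0:
        top = np.argsort(-np.abs(expl.mean_weight))[:top_k]
        for s in top:
            tint = np.array([60.0, 200.0, 60.0]) if expl.mean_weight[s] >= 0 \
                else np.array([220.0, 50.0, 50.0])
            where = expl.segment_map == s
            rgb[where] = 0.55 * rgb[where] + 0.45 * tint
        # legend: green = supports prediction, red = opposes
        h = img.shape[0]
        sw = max(3, h // 24)
        rgb[h - sw:h, 0:sw] = [60, 200, 60]
        rgb[h - sw:h, sw + 1:2 * sw + 1] = [220, 50, 50]
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
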