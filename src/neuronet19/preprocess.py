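"""Brain-extraction preprocessing chain.

The chain standardizes a raster to a fixed-size gray image, then isolates
the brain before handing the image to the classifier:

    standardize -> Gaussian blur -> Otsu threshold -> contour (connected
    component) area filter -> filled-mask overlay -> crop -> power-law
    transform -> final resize.

The binary mask is computed from a *blurred working copy* but applied to
the un-blurred standardized image, so classification sees full detail.
"Contour area" is the filled connected-component pixel count; components
below ``min_contour_area`` (specks, annotations, noise) are ignored, and
the largest remaining component defines the crop rectangle.  The
power-law (gamma) step ``P = k * Q**beta`` on [0, 1]-normalized
intensities emphasizes bright structure; ``beta = 1.5`` by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "BinaryMask",
    "RegionOfInterest",
    "standardize",
    "gaussian_kernel",
    "gaussian_blur",
    "otsu_threshold",
    "brain_roi",
    "select_brain_component",
    "apply_mask_and_crop",
    "power_law",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the brain-extraction chain.

    ``min_contour_area`` is interpreted in pixels at the ``target_size``
    working resolution (resizing happens first).  ``foreground_bright``
    selects the polarity of the threshold: brain brighter than background
    (the MRI-on-black convention) keeps pixels ``> T``.
    """

    target_size: int = 128
    blur_kernel_n: int = 11
    min_contour_area: int = 1000
    gamma_beta: float = 1.5
    gamma_gain: float = 1.0
    foreground_bright: bool = True

    def validate(self) -> None:
        if self.blur_kernel_n < 3 or self.blur_kernel_n % 2 == 0:
            raise ValueError("blur_kernel_n must be odd and >= 3")
        if self.min_contour_area < 1:
            raise ValueError("min_contour_area must be >= 1")
        if self.gamma_beta <= 0 or self.gamma_gain <= 0:
            raise ValueError("gamma_beta and gamma_gain must be > 0")
        if self.target_size < 32:
            raise ValueError("target_size must be >= 32")


@dataclass
class BinaryMask:
    """Thresholding result: boolean foreground plus the threshold used.

    ``degenerate`` is set when no gray level splits the histogram into two
    non-empty classes (constant image); callers fall back to a full-image
    region of interest.
    """

    pixels: np.ndarray
    threshold_used: int | None
    degenerate: bool = False


@dataclass(frozen=True)
class RegionOfInterest:
    """Crop rectangle: ``x, y`` top-left (0-based), ``w, h`` extent.

    ``area`` is the filled pixel count of the selected component;
    ``fallback`` flags that no component passed the area filter and the
    full image was returned instead.
    """

    x: int
    y: int
    w: int
    h: int
    area: int
    fallback: bool = False


def _to_pil(image) -> Image.Image:
    if isinstance(image, Image.Image):
        return image
    if isinstance(image, (str, Path)):
        try:
            img = Image.open(image)
            img.load()
            return img
        except Exception as exc:  # undecodable / missing
            raise ValueError(f"cannot decode image {image!r}: {exc}") from exc
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 2:
        return Image.fromarray(arr.astype(np.uint8), mode="L")
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return Image.fromarray(arr.astype(np.uint8))
    raise ValueError(f"unsupported image shape {arr.shape}")


def standardize(image, size: int = 128) -> np.ndarray:
    """Decode, convert to single-channel luminance, resize to size x size.

    Already-conforming inputs pass through with values unchanged.  Aspect
    ratio is not preserved (bilinear resize straight to the square target,
    the usual convention for fixed-input networks).
    """
    img = _to_pil(image)
    if img.mode != "L":
        img = img.convert("L")
    if img.size != (size, size):
        img = img.resize((size, size), Image.BILINEAR)
    return np.asarray(img, dtype=np.uint8)


def gaussian_kernel(n: int) -> np.ndarray:
    """Normalized n x n Gaussian kernel with sigma = (n - 1) / 6."""
    if n < 1 or n % 2 == 0:
        raise ValueError("kernel dimension must be odd")
    sigma = (n - 1) / 6.0
    half = n // 2
    a = np.arange(-half, half + 1, dtype=np.float64)
    aa, bb = np.meshgrid(a, a, indexing="ij")
    k = np.exp(-(aa ** 2 + bb ** 2) / (2.0 * sigma ** 2)) / (2.0 * np.pi * sigma ** 2)
    return k / k.sum()


def gaussian_blur(image: np.ndarray, n: int = 11) -> np.ndarray:
    """Convolve with the normalized Gaussian kernel; edges replicate.

    Returns a float array so downstream oracles can compare exactly; round
    to uint8 when a gray image is needed.
    """
    k = gaussian_kernel(n)
    return ndimage.correlate(np.asarray(image, dtype=np.float64), k, mode="nearest")


def otsu_threshold(image: np.ndarray, foreground_bright: bool = True) -> BinaryMask:
    """Otsu's threshold: maximize sigma^2(T) = w1 w2 (mu1 - mu2)^2.

    Class 1 is pixels <= T, class 2 pixels > T; the lowest maximizing T
    wins ties.  Foreground is the bright side by default (brain on black).
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    vals = np.clip(np.rint(img), 0, 255).astype(np.int64)
    hist = np.bincount(vals.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    p = hist / total
    omega1 = np.cumsum(p)                     # P(value <= T), T = 0..255
    mu_cum = np.cumsum(p * np.arange(256))
    mu_total = mu_cum[-1]
    omega2 = 1.0 - omega1
    valid = (omega1 > 0) & (omega2 > 0)
    if not valid.any():
        return BinaryMask(pixels=np.zeros(img.shape, dtype=bool),
                          threshold_used=None, degenerate=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = mu_cum / omega1
        mu2 = (mu_total - mu_cum) / omega2
    score = np.where(valid, omega1 * omega2 * (mu1 - mu2) ** 2, -np.inf)
    t = int(np.argmax(score))                 # first max -> lowest T
    fg = vals > t if foreground_bright else vals <= t
    return BinaryMask(pixels=fg, threshold_used=t, degenerate=False)


def _components(mask: np.ndarray):
    """8-connected components with their filled masks and areas."""
    structure = np.ones((3, 3), dtype=int)
    labels, n = ndimage.label(mask, structure=structure)
    out = []
    for lab, sl in zip(range(1, n + 1), ndimage.find_objects(labels)):
        comp = labels[sl] == lab
        filled = ndimage.binary_fill_holes(comp)
        out.append((lab, sl, filled, int(filled.sum())))
    return out


def select_brain_component(mask: BinaryMask, min_area: int = 1000):
    """Pick the largest filled component with area >= min_area.

    Returns ``(filled_mask, roi)``.  scipy labels components in raster-scan
    order of first pixel, so on an area tie the component whose top-left
    pixel comes first in row-major order keeps the lower label and wins.
    If nothing qualifies (or the mask is degenerate/empty) the full image
    is returned with ``fallback=True``.
    """
    pix = mask.pixels
    h, w = pix.shape
    best = None
    if not mask.degenerate and pix.any():
        for lab, sl, filled, area in _components(pix):
            if area >= min_area and (best is None or area > best[3]):
                best = (lab, sl, filled, area)
    if best is None:
        roi = RegionOfInterest(0, 0, w, h, area=h * w, fallback=True)
        return np.ones((h, w), dtype=bool), roi
    _, sl, filled, area = best
    full = np.zeros((h, w), dtype=bool)
    full[sl] = filled
    ys, xs = sl[0], sl[1]
    roi = RegionOfInterest(x=int(xs.start), y=int(ys.start),
                           w=int(xs.stop - xs.start), h=int(ys.stop - ys.start),
                           area=area, fallback=False)
    return full, roi


def brain_roi(mask: BinaryMask, min_area: int = 1000) -> RegionOfInterest:
    """Bounding rectangle of the selected brain component (see above)."""
    _, roi = select_brain_component(mask, min_area)
    return roi


def apply_mask_and_crop(image: np.ndarray, mask: np.ndarray | BinaryMask,
                        roi: RegionOfInterest) -> np.ndarray:
    """Zero everything outside the (filled) mask, then crop to the ROI."""
    img = np.asarray(image)
    pix = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    if pix.shape != img.shape:
        raise ValueError("mask and image shapes differ")
    h, w = img.shape
    if not (0 <= roi.x and roi.x + roi.w <= w and 0 <= roi.y and roi.y + roi.h <= h
            and roi.w >= 1 and roi.h >= 1):
        raise ValueError(f"ROI {roi} outside image bounds {(h, w)}")
    out = np.where(pix, img, 0)
    return out[roi.y:roi.y + roi.h, roi.x:roi.x + roi.w]


def power_law(image: np.ndarray, k: float = 1.0, beta: float = 1.5) -> np.ndarray:
    """Gamma transform: Q = pixel/255, P = clip(k * Q**beta, 0, 1) * 255."""
    if k <= 0 or beta <= 0:
        raise ValueError("k and beta must be > 0")
    q = np.asarray(image, dtype=np.float64) / 255.0
    p = np.clip(k * np.power(q, beta), 0.0, 1.0)
    return np.rint(p * 255.0).astype(np.uint8)


def _resize_gray(image: np.ndarray, size: int) -> np.ndarray:
    if image.shape == (size, size):
        return image.astype(np.uint8)
    pil = Image.fromarray(image.astype(np.uint8), mode="L")
    return np.asarray(pil.resize((size, size), Image.BILINEAR), dtype=np.uint8)


def preprocess_pipeline(image, config: PreprocessConfig = PreprocessConfig(),
                        return_stages: bool = False):
    """Full chain; deterministic, always returns target_size x target_size uint8.

    With ``return_stages=True`` also returns a dict of the intermediate
    images/objects (for debugging dumps): standardized, blurred, mask, roi,
    masked_cropped, power, output.
    """
    config.validate()
    std = standardize(image, config.target_size)
    blurred = gaussian_blur(std, config.blur_kernel_n)
    mask = otsu_threshold(blurred, foreground_bright=config.foreground_bright)
    if mask.degenerate:
        log.warning("degenerate Otsu threshold (constant image); "
                    "falling back to full-image ROI")
    filled, roi = select_brain_component(mask, config.min_contour_area)
    cropped = apply_mask_and_crop(std, filled, roi)
    powered = power_law(cropped, k=config.gamma_gain, beta=config.gamma_beta)
    out = _resize_gray(powered, config.target_size)
    if return_stages:
        return out, {
            "standardized": std,
            "blurred": blurred,
            "mask": mask,
            "roi": roi,
            "filled": filled,
            "masked_cropped": cropped,
            "power": powered,
            "output": out,
        }
    return out
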