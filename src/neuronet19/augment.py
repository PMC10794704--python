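"""Affine training-set augmentation.

The five operators — rotation, shear, zoom, width/height shift and
horizontal flip — are composed into a single resampling pass (one bilinear
interpolation about the image centre) so repeated warps do not compound
blur; the optional flip is applied afterwards as an exact mirror.
Out-of-frame samples take the nearest edge value, which avoids black
borders that would confuse contour-sensitive features.  Augmentation is
applied to the training stream only; validation and test images never pass
through this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy import ndimage

__all__ = [
    "AugmentConfig",
    "AffineParams",
    "sample_params",
    "affine_matrix",
    "apply_affine",
    "augment_stream",
]

_DEFAULT_ORDER = ("rotate", "shear", "zoom", "shift")


@dataclass(frozen=True)
class AugmentConfig:
    """Operator ranges: rotation 0-25 deg, shear 0-0.2, zoom 0-0.2,
    width/height shift -0.2..0.2 (fraction of the dimension), horizontal
    flip enabled.  ``symmetric_rotation`` widens rotation to +/-max."""

    rotation_max_deg: float = 25.0
    horizontal_flip: bool = True
    shear_max: float = 0.2
    zoom_max: float = 0.2
    width_shift_max: float = 0.2
    height_shift_max: float = 0.2
    symmetric_rotation: bool = False
    compose_order: tuple[str, ...] = _DEFAULT_ORDER

    def validate(self) -> None:
        for name in ("rotation_max_deg", "shear_max", "zoom_max",
                     "width_shift_max", "height_shift_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if set(self.compose_order) != set(_DEFAULT_ORDER):
            raise ValueError("compose_order must be a permutation of "
                             f"{_DEFAULT_ORDER}")


@dataclass(frozen=True)
class AffineParams:
    """One sampled transform: rotation angle theta (degrees), shear factor
    lam, zoom factors (zx, zy), pixel shifts (dx, dy), and the flip flag."""

    theta: float = 0.0
    flip: bool = False
    lam: float = 0.0
    zx: float = 1.0
    zy: float = 1.0
    dx: float = 0.0
    dy: float = 0.0

    @property
    def is_identity(self) -> bool:
        return (self.theta == 0.0 and not self.flip and self.lam == 0.0
                and self.zx == 1.0 and self.zy == 1.0
                and self.dx == 0.0 and self.dy == 0.0)


def sample_params(config: AugmentConfig, rng: np.random.Generator,
                  shape: tuple[int, int] = (128, 128)) -> AffineParams:
    """Draw each parameter uniformly from its configured range.

    ``shape`` is the (H, W) of the images the params will be applied to;
    shifts are fractions of those dimensions converted to pixels.
    """
    config.validate()
    h, w = shape
    lo_rot = -config.rotation_max_deg if config.symmetric_rotation else 0.0
    theta = float(rng.uniform(lo_rot, config.rotation_max_deg))
    lam = float(rng.uniform(0.0, config.shear_max))
    zx = float(rng.uniform(1.0, 1.0 + config.zoom_max))
    zy = float(rng.uniform(1.0, 1.0 + config.zoom_max))
    dx = float(rng.uniform(-config.width_shift_max, config.width_shift_max) * w)
    dy = float(rng.uniform(-config.height_shift_max, config.height_shift_max) * h)
    flip = bool(config.horizontal_flip and rng.random() < 0.5)
    return AffineParams(theta=theta, flip=flip, lam=lam, zx=zx, zy=zy, dx=dx, dy=dy)


def _op_matrix(op: str, p: AffineParams) -> np.ndarray:
    m = np.eye(3)
    if op == "rotate":
        t = np.deg2rad(p.theta)
        m[:2, :2] = [[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]]
    elif op == "shear":
        m[0, 1] = p.lam
    elif op == "zoom":
        m[0, 0], m[1, 1] = p.zx, p.zy
    elif op == "shift":
        m[0, 2], m[1, 2] = p.dx, p.dy
    else:
        raise ValueError(f"unknown affine op {op!r}")
    return m


def affine_matrix(params: AffineParams,
                  order: tuple[str, ...] = _DEFAULT_ORDER) -> np.ndarray:
    """Forward 3x3 homogeneous matrix in (x, y) coordinates about the origin.

    Ops listed first in ``order`` are applied first:
    p' = M_last @ ... @ M_first @ p.  The flip is not included (it is an
    exact post-warp mirror).
    """
    m = np.eye(3)
    for op in order:
        m = _op_matrix(op, params) @ m
    return m


def apply_affine(image: np.ndarray, params: AffineParams,
                 order: tuple[str, ...] = _DEFAULT_ORDER) -> np.ndarray:
    """Warp about the image centre in one bilinear pass, then flip.

    Identity parameters return a bit-identical copy.  Out-of-frame pixels
    replicate the nearest edge value; the output keeps shape and dtype.
    """
    img = np.asarray(image)
    if params.is_identity:
        return img.copy()
    h, w = img.shape[:2]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    center = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    uncenter = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    fwd = center @ affine_matrix(params, order) @ uncenter
    inv = np.linalg.inv(fwd)
    # (x, y) -> (row, col): swap both axes of the linear part and offset
    matrix_rc = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    offset_rc = np.array([inv[1, 2], inv[0, 2]])
    warped = ndimage.affine_transform(img.astype(np.float64), matrix_rc,
                                      offset=offset_rc, order=1, mode="nearest")
    if params.flip:
        warped = warped[:, ::-1]
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return np.clip(np.rint(warped), info.min, info.max).astype(img.dtype)
    return warped.astype(img.dtype)


def augment_stream(dataset, config: AugmentConfig,
                   rng: np.random.Generator) -> Iterator[tuple[np.ndarray, int]]:
    """Yield one randomly augmented copy of every item (one epoch pass).

    ``dataset`` is either an iterable of ``(gray_image, label)`` pairs or a
    :class:`~neuronet19.data.DatasetIndex` whose files are loaded as
    grayscale.  Labels pass through unchanged.
    """
    from .data import DatasetIndex

    if isinstance(dataset, DatasetIndex):
        items: Iterable = ((_load_gray(path), label) for path, label in dataset.entries)
    else:
        items = dataset
    for image, label in items:
        params = sample_params(config, rng, shape=np.asarray(image).shape[:2])
        yield apply_affine(image, params, order=config.compose_order), label


def _load_gray(path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img.convert("L"), dtype=np.uint8)
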