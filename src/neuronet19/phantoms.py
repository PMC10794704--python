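"""Synthetic MRI-like phantom generator for the four tumor classes.

Real brain MRI slices show a bright brain on a dark, mildly noisy
background, which is exactly the structure the brain-extraction stage
(Otsu threshold + largest filled contour) relies on.  The generator
reproduces that structure with a bright axis-aligned ellipse plus
class-conditional lesions:

* ``glioma`` — an irregular multi-lobe blob with heterogeneous intensity,
* ``meningioma`` — a well-defined circle of uniform intensity,
* ``pituitary`` — a small circle near the base (lower middle) of the brain,
* ``notumor`` — no lesion.

Small bright "distractor" specks are scattered on the background so the
minimum-contour-area filter of the preprocessing chain is exercised; every
speck stays below the area threshold while the brain ellipse always
exceeds it.  Classes are deliberately separable by lesion morphology so a
scaled-down classifier has a learnable signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

CLASS_NAMES = ("glioma", "meningioma", "notumor", "pituitary")
GLIOMA, MENINGIOMA, NOTUMOR, PITUITARY = range(4)

__all__ = [
    "CLASS_NAMES",
    "Bbox",
    "PhantomSpec",
    "PhantomImage",
    "generate_phantom",
    "generate_dataset",
]


@dataclass(frozen=True)
class Bbox:
    """Axis-aligned bounding box: ``x, y`` top-left (0-based), ``w, h`` extent."""

    x: int
    y: int
    w: int
    h: int

    @staticmethod
    def of_mask(mask: np.ndarray) -> "Bbox":
        ys, xs = np.nonzero(mask)
        if ys.size == 0:
            raise ValueError("empty mask has no bounding box")
        return Bbox(int(xs.min()), int(ys.min()),
                    int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))

    def contains(self, other: "Bbox") -> bool:
        return (self.x <= other.x and self.y <= other.y
                and other.x + other.w <= self.x + self.w
                and other.y + other.h <= self.y + self.h)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic slices.

    Lengths are expressed in pixels at a 128-px reference resolution and
    scale linearly with ``image_size``.  Intensities are gray levels in
    [0, 255]; ``noise_sd`` is the standard deviation of the additive
    Gaussian noise applied before clipping.
    """

    image_size: int = 128
    brain_axes_range: tuple[float, float] = (0.30, 0.42)
    brain_intensity: float = 140.0
    background_intensity: float = 8.0
    noise_sd: float = 6.0
    # class-conditional lesion descriptors (reference resolution 128 px)
    glioma_lobes: tuple[int, int] = (3, 5)
    glioma_lobe_radius: tuple[float, float] = (6.0, 12.0)
    glioma_intensity: tuple[float, float] = (90.0, 220.0)
    meningioma_radius: tuple[float, float] = (8.0, 14.0)
    meningioma_intensity: float = 200.0
    pituitary_radius: tuple[float, float] = (4.0, 8.0)
    pituitary_intensity: float = 210.0
    lesion_margin: float = 4.0
    distractor_count: int = 3
    distractor_radius: tuple[float, float] = (2.0, 6.0)
    distractor_intensity: float = 180.0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        lo, hi = self.brain_axes_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("brain_axes_range must lie in (0, 0.5)")

    @property
    def scale(self) -> float:
        return self.image_size / 128.0


@dataclass
class PhantomImage:
    """Rendered phantom plus ground truth used by downstream tests."""

    pixels: np.ndarray  # (H, W) uint8
    label: int
    lesion_bbox: Bbox | None
    brain_bbox: Bbox
    lesion_mask: np.ndarray | None = None
    brain_mask: np.ndarray | None = None


def _disk_mask(size: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _inner_point(rng, cx, cy, a, b, clearance):
    """Uniform point whose `clearance`-disk fits inside the ellipse."""
    ea, eb = a - clearance, b - clearance
    if ea <= 1 or eb <= 1:
        return cx, cy
    while True:
        u, v = rng.uniform(-1, 1, size=2)
        if u * u + v * v <= 1.0:
            return cx + u * ea, cy + v * eb


def _render_lesion(img, rng, label, spec, inner):
    """Paint the class lesion inside `inner` (margin-eroded brain ellipse)."""
    size = spec.image_size
    s = spec.scale
    cx, cy, a, b = inner["cx"], inner["cy"], inner["a"], inner["b"]
    margin = spec.lesion_margin * s

    if label == MENINGIOMA:
        r = rng.uniform(*spec.meningioma_radius) * s
        lx, ly = _inner_point(rng, cx, cy, a, b, r + margin)
        mask = _disk_mask(size, lx, ly, r)
        img[mask] = spec.meningioma_intensity
        return mask

    if label == PITUITARY:
        r = rng.uniform(*spec.pituitary_radius) * s
        # base of the brain: lower-middle fifth of the ellipse
        lx = cx + rng.uniform(-0.2, 0.2) * a
        ly = cy + rng.uniform(0.30, 0.55) * b
        ly = min(ly, cy + b - r - margin)
        mask = _disk_mask(size, lx, ly, r)
        img[mask] = spec.pituitary_intensity
        return mask

    if label == GLIOMA:
        n_lobes = rng.integers(spec.glioma_lobes[0], spec.glioma_lobes[1] + 1)
        r_hi = spec.glioma_lobe_radius[1] * s
        bx, by = _inner_point(rng, cx, cy, a, b, 2.2 * r_hi + margin)
        mask = np.zeros((size, size), dtype=bool)
        for _ in range(n_lobes):
            r = rng.uniform(*spec.glioma_lobe_radius) * s
            ox, oy = rng.uniform(-1.0, 1.0, size=2) * r_hi
            mask |= _disk_mask(size, bx + ox, by + oy, r)
        # clip to the eroded ellipse so the lesion stays strictly inside
        mask &= _ellipse_mask(size, cx, cy, a - margin, b - margin)
        lo, hi = spec.glioma_intensity
        field_ = ndimage.gaussian_filter(rng.uniform(lo, hi, size=(size, size)), 1.5 * s)
        field_ = lo + (field_ - field_.min()) / max(float(np.ptp(field_)), 1e-9) * (hi - lo)
        img[mask] = field_[mask]
        return mask

    return None  # notumor


def generate_phantom(label: int, spec: PhantomSpec = PhantomSpec(),
                     seed: int = 0) -> PhantomImage:
    """Render one phantom slice; deterministic in ``(label, spec, seed)``."""
    if label not in (0, 1, 2, 3):
        raise ValueError(f"label must be in 0..3, got {label!r}")
    spec.validate()
    rng = np.random.default_rng([int(seed), int(label)])
    size = spec.image_size

    img = np.full((size, size), spec.background_intensity, dtype=np.float64)

    # brain ellipse, jittered about the image centre
    cx = size / 2 + rng.uniform(-0.04, 0.04) * size
    cy = size / 2 + rng.uniform(-0.04, 0.04) * size
    a = rng.uniform(*spec.brain_axes_range) * size
    b = rng.uniform(*spec.brain_axes_range) * size
    brain = _ellipse_mask(size, cx, cy, a, b)
    img[brain] = spec.brain_intensity

    lesion = _render_lesion(img, rng, label, spec,
                            {"cx": cx, "cy": cy, "a": a, "b": b})

    # background distractor specks, each well below the contour-area filter
    dilated = _ellipse_mask(size, cx, cy, a + 10 * spec.scale, b + 10 * spec.scale)
    for _ in range(spec.distractor_count):
        r = rng.uniform(*spec.distractor_radius) * spec.scale
        for _attempt in range(50):
            dx, dy = rng.uniform(r + 1, size - r - 1, size=2)
            if not dilated[int(dy), int(dx)]:
                img[_disk_mask(size, dx, dy, r)] = spec.distractor_intensity
                break

    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return PhantomImage(
        pixels=pixels,
        label=int(label),
        lesion_bbox=Bbox.of_mask(lesion) if lesion is not None and lesion.any() else None,
        brain_bbox=Bbox.of_mask(brain),
        lesion_mask=lesion if lesion is not None and lesion.any() else None,
        brain_mask=brain,
    )


def generate_dataset(spec: PhantomSpec, n_per_class: int, seed: int,
                     out_dir: str | Path):
    """Write a class-per-directory PNG tree and return its index.

    Layout mirrors the real dataset: ``<out>/<class_name>/<index>.png`` with
    class names exactly ``glioma``, ``meningioma``, ``notumor``,
    ``pituitary``.  Deterministic in ``(spec, n_per_class, seed)``.
    """
    from .data import DatasetIndex  # local import to avoid a cycle

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    entries: list[tuple[Path, int]] = []
    for ci, cname in enumerate(CLASS_NAMES):
        cdir = out_dir / cname
        cdir.mkdir(parents=True, exist_ok=True)
        for i in range(n_per_class):
            child = int(np.random.SeedSequence([int(seed), ci, i]).generate_state(1)[0])
            ph = generate_phantom(ci, spec, seed=child)
            path = cdir / f"{i:04d}.png"
            Image.fromarray(ph.pixels).save(path)
            entries.append((path, ci))
    return DatasetIndex(entries=entries, class_names=list(CLASS_NAMES), split="train")


def lesion_area(ph: PhantomImage) -> int:
    """Ground-truth lesion pixel count (0 for notumor)."""
    return 0 if ph.lesion_mask is None else int(ph.lesion_mask.sum())
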