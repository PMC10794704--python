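"""Dataset indexing for class-per-directory image trees.

The canonical layout mirrors the public brain-tumor MRI dataset:

    <root>/glioma/*.jpg|png
    <root>/meningioma/...
    <root>/notumor/...
    <root>/pituitary/...

Class indices are the lexicographic rank of the directory names (byte
order, locale-independent), so for the canonical tree glioma -> 0,
meningioma -> 1, notumor -> 2, pituitary -> 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

log = logging.getLogger(__name__)

__all__ = ["DatasetIndex", "load_image_folder", "load_arrays"]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class DatasetIndex:
    """Ordered list of (file path, class index) plus the class vocabulary."""

    entries: list[tuple[Path, int]]
    class_names: list[str]
    split: str = "train"
    skipped: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> np.ndarray:
        return np.array([label for _, label in self.entries], dtype=np.int64)

    def paths(self) -> list[Path]:
        return [p for p, _ in self.entries]

    def per_class_counts(self) -> dict[str, int]:
        y = self.labels()
        return {name: int((y == i).sum()) for i, name in enumerate(self.class_names)}


def _decodable(path: Path) -> bool:
    try:
        with Image.open(path) as img:
            img.verify()
        return True
    except (UnidentifiedImageError, OSError, SyntaxError):
        return False


def load_image_folder(root: str | Path, split: str = "train",
                      check_decodable: bool = True) -> DatasetIndex:
    """Index a class-per-directory tree with deterministic ordering.

    Classes and files are sorted lexicographically (codepoint order);
    undecodable files are skipped with a warning and counted in
    ``index.skipped``.  Empty roots or class directories raise.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    class_dirs = sorted((d for d in root.iterdir() if d.is_dir()),
                        key=lambda d: d.name)
    if not class_dirs:
        raise ValueError(f"dataset root {root} contains no class directories")
    entries: list[tuple[Path, int]] = []
    skipped = 0
    class_names = [d.name for d in class_dirs]
    for ci, cdir in enumerate(class_dirs):
        files = sorted(p for p in cdir.iterdir()
                       if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES)
        kept = 0
        for p in files:
            if check_decodable and not _decodable(p):
                log.warning("skipping undecodable image %s", p)
                skipped += 1
                continue
            entries.append((p, ci))
            kept += 1
        if kept == 0:
            raise ValueError(f"class directory {cdir} contains no decodable images")
    return DatasetIndex(entries=entries, class_names=class_names,
                        split=split, skipped=skipped)


def load_arrays(index: DatasetIndex, preprocess_config=None,
                size: int | None = None):
    """Load every indexed image into a (N, H, W) uint8 stack plus labels.

    With ``preprocess_config`` each image runs through the full
    brain-extraction pipeline; otherwise images are standardized (gray,
    resized to ``size`` or the pipeline default 128).
    """
    from .preprocess import preprocess_pipeline, standardize

    images = []
    for path, _ in index.entries:
        if preprocess_config is not None:
            images.append(preprocess_pipeline(path, preprocess_config))
        else:
            images.append(standardize(path, size or 128))
    return np.stack(images), index.labels()
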