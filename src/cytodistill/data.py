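"""Image-folder datasets, stratified 3:1:1 splitting, and augmentation.

Datasets follow the one-subdirectory-per-class layout used by public
single-cell cytology collections; items may be file paths (real data)
or in-memory arrays (the synthetic generator).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize, rotate as _sk_rotate

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp"}
SPLITS = ("train", "val", "test")


class DataError(ValueError):
    """Raised for malformed or degenerate dataset inputs."""


@dataclass
class LabeledImageSet:
    """Images with integer class labels and an optional split assignment.

    ``items`` holds (image, class_index) pairs where the image is either a
    path or an (H, W, 3) float array in [0, 1]; ``split_assignment`` maps
    item index -> one of "train"/"val"/"test".
    """

    items: list
    class_names: list
    split_assignment: dict | None = None
    item_meta: list | None = None

    def __post_init__(self):
        for _, ci in self.items:
            if not 0 <= ci < len(self.class_names):
                raise DataError(f"class index {ci} out of range for "
                                f"{len(self.class_names)} classes")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def labels(self) -> np.ndarray:
        return np.array([ci for _, ci in self.items], dtype=np.int64)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def indices(self, split: str | None = None) -> list:
        if split is None:
            return list(range(len(self.items)))
        if self.split_assignment is None:
            raise DataError("dataset has no split assignment; call split_dataset first")
        return [i for i in range(len(self.items)) if self.split_assignment[i] == split]

    def load_array(self, i: int) -> np.ndarray:
        """Resolve item ``i`` to an (H, W, 3) float32 array in [0, 1]."""
        img, _ = self.items[i]
        if isinstance(img, np.ndarray):
            return img
        from PIL import Image

        with Image.open(img) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
        return arr

    def write_split_manifest(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["filename", "class", "split"])
            for i, (img, ci) in enumerate(self.items):
                name = str(img) if not isinstance(img, np.ndarray) else f"item_{i}"
                split = self.split_assignment[i] if self.split_assignment else ""
                writer.writerow([name, self.class_names[ci], split])


def load_image_folder(root_path, verify: bool = False) -> LabeledImageSet:
    """Read a class-subdirectory image folder into a LabeledImageSet.

    Class names are the subdirectory names, sorted lexicographically;
    files are enumerated in sorted order, so the result is deterministic.
    With ``verify=True`` each file is opened and undecodable images are
    skipped with a logged warning (by default files are enumerated by
    extension only and decoded lazily).
    """
    root = Path(root_path)
    if not root.is_dir():
        raise DataError(f"dataset root {root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) < 2:
        raise DataError(f"need at least 2 class subdirectories under {root}, "
                        f"found {len(class_dirs)}")
    items = []
    class_names = [d.name for d in class_dirs]
    for ci, cdir in enumerate(class_dirs):
        files = sorted(p for p in cdir.iterdir()
                       if p.suffix.lower() in IMAGE_EXTENSIONS)
        if not files:
            raise DataError(f"class directory {cdir} contains no image files")
        for p in files:
            if verify:
                try:
                    from PIL import Image

                    with Image.open(p) as im:
                        im.verify()
                except Exception:
                    logger.warning("skipping unreadable image %s", p)
                    continue
            items.append((p, ci))
    return LabeledImageSet(items=items, class_names=class_names)


def _largest_remainder(n: int, weights) -> list:
    """Apportion n into integer parts proportional to weights."""
    weights = np.asarray(weights, dtype=np.float64)
    quotas = n * weights / weights.sum()
    parts = np.floor(quotas).astype(int)
    rem = n - parts.sum()
    order = np.argsort(-(quotas - parts))
    for k in range(rem):
        parts[order[k]] += 1
    return parts.tolist()


def split_dataset(dataset: LabeledImageSet, ratios=(3, 1, 1),
                  seed: int = 0) -> LabeledImageSet:
    """Stratified random split into train/val/test at the given ratios.

    Within each class, items are shuffled with a generator seeded by
    ``seed`` and apportioned by largest remainder, so every class
    contributes to every split (class size must be >= number of splits
    at minimum one item per slot) and per-class proportions are within
    one item of the exact ratios.
    """
    if len(ratios) != len(SPLITS):
        raise DataError(f"expected {len(SPLITS)} ratios, got {len(ratios)}")
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    assignment = {}
    for ci, cname in enumerate(dataset.class_names):
        idx = np.flatnonzero(labels == ci)
        min_items = int(sum(ratios))
        if len(idx) < min_items:
            raise DataError(f"class {cname!r} has only {len(idx)} items; "
                            f"need at least {min_items} for a "
                            f"{':'.join(map(str, ratios))} split")
        rng.shuffle(idx)
        parts = _largest_remainder(len(idx), ratios)
        if min(parts) == 0:  # guarantee one item per split slot
            for s_empty in [s for s in range(len(parts)) if parts[s] == 0]:
                donor = int(np.argmax(parts))
                parts[donor] -= 1
                parts[s_empty] += 1
        start = 0
        for split, count in zip(SPLITS, parts):
            for i in idx[start:start + count]:
                assignment[int(i)] = split
            start += count
    return LabeledImageSet(items=dataset.items, class_names=dataset.class_names,
                           split_assignment=assignment, item_meta=dataset.item_meta)


@dataclass
class AugmentPolicy:
    """Train-time augmentation: random area-scaled crop, rotation, and
    horizontal/vertical flips, followed by a resize to ``output_size``.

    The degenerate policy (unit crop range, 0 degrees, zero flip
    probabilities) reduces exactly to ``resize_image``.
    """

    crop_scale_range: tuple = (0.7, 1.0)
    rotation_degrees: float = 15.0
    horizontal_flip_p: float = 0.5
    vertical_flip_p: float = 0.5
    output_size: int = 64

    def __post_init__(self):
        lo, hi = self.crop_scale_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"crop_scale_range must be within (0, 1], got {(lo, hi)}")
        for fname in ("horizontal_flip_p", "vertical_flip_p"):
            p = getattr(self, fname)
            if not 0 <= p <= 1:
                raise ValueError(f"{fname} must be in [0, 1], got {p}")
        if self.rotation_degrees < 0:
            raise ValueError("rotation_degrees must be >= 0")

    @classmethod
    def none(cls, output_size: int) -> "AugmentPolicy":
        return cls(crop_scale_range=(1.0, 1.0), rotation_degrees=0.0,
                   horizontal_flip_p=0.0, vertical_flip_p=0.0,
                   output_size=output_size)


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Resize an (H, W, C) float image to (size, size, C); identity when
    the image already has the target size."""
    if image.shape[0] == size and image.shape[1] == size:
        return image
    out = _sk_resize(image, (size, size), order=1, mode="edge",
                     anti_aliasing=image.shape[0] > size, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def augment(image: np.ndarray, policy: AugmentPolicy, rng_seed) -> np.ndarray:
    """Apply the augmentation policy; deterministic per (image, policy, seed).

    Operation order: rotate -> random crop (area fraction drawn from
    ``crop_scale_range``) -> flips -> resize to ``output_size``.  Values
    stay in [0, 1]; labels/metadata are untouched (augmentation operates
    on pixels only).
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    img = np.asarray(image, dtype=np.float32)
    if policy.rotation_degrees > 0:
        angle = float(rng.uniform(-policy.rotation_degrees, policy.rotation_degrees))
        img = _sk_rotate(img, angle, mode="edge", order=1,
                         preserve_range=True).astype(np.float32)
    lo, hi = policy.crop_scale_range
    if (lo, hi) != (1.0, 1.0):
        area = float(rng.uniform(lo, hi))
        side_h = max(1, int(round(img.shape[0] * np.sqrt(area))))
        side_w = max(1, int(round(img.shape[1] * np.sqrt(area))))
        top = int(rng.integers(0, img.shape[0] - side_h + 1))
        left = int(rng.integers(0, img.shape[1] - side_w + 1))
        img = img[top:top + side_h, left:left + side_w]
    if policy.horizontal_flip_p > 0 and rng.uniform() < policy.horizontal_flip_p:
        img = img[:, ::-1]
    if policy.vertical_flip_p > 0 and rng.uniform() < policy.vertical_flip_p:
        img = img[::-1, :]
    out = resize_image(np.ascontiguousarray(img), policy.output_size)
    return np.clip(out, 0.0, 1.0)


def compute_norm_stats(dataset: LabeledImageSet, split: str | None = "train",
                       size: int | None = None):
    """Per-channel mean/std over a split (resized if ``size`` is given).

    Computed from the training split rather than fixed constants because
    synthetic and real cytology data have very different statistics.
    """
    idx = dataset.indices(split)
    if not idx:
        raise DataError(f"no items in split {split!r}")
    acc = np.zeros(3, dtype=np.float64)
    acc2 = np.zeros(3, dtype=np.float64)
    npix = 0
    for i in idx:
        arr = dataset.load_array(i)
        if size is not None:
            arr = resize_image(arr, size)
        acc += arr.reshape(-1, 3).sum(axis=0)
        acc2 += (arr.reshape(-1, 3) ** 2).sum(axis=0)
        npix += arr.shape[0] * arr.shape[1]
    mean = acc / npix
    std = np.sqrt(np.maximum(acc2 / npix - mean ** 2, 1e-12))
    return mean.astype(np.float32), std.astype(np.float32)
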