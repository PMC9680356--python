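"""Synthetic single-cell image generator.

Renders 5 classes of grayscale "cells" (replicated to 3 channels) whose
classes differ along the axes that separate real cervical cell types:
nucleus size, nucleo-cytoplasmic (N/C) ratio, cytoplasm boundary
irregularity, mean intensities and intra-cytoplasm texture frequency.
The default classes are ordered by increasing N/C ratio, mimicking the
normal-to-abnormal morphology gradient of cervical cytology.

Every image is a pure function of (morphology, seed), so datasets are
bit-reproducible and all training code is testable without downloads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import LabeledImageSet

__all__ = [
    "ClassMorphology", "SyntheticSpec", "default_classes",
    "render_cell", "generate_dataset", "write_image_folder",
]

#: amplitude of the radial ring texture inside the cytoplasm
_TEXTURE_AMPLITUDE = 0.06
#: harmonics used for the boundary perturbation
_BOUNDARY_HARMONICS = (2, 3, 4, 5)


@dataclass(frozen=True)
class ClassMorphology:
    """Morphological parameter ranges for one synthetic cell class.

    Radii are fractions of the image side; intensities are mean grayscale
    levels in [0, 1]; ``boundary_irregularity`` is the relative amplitude
    of the radial perturbation of the cytoplasm outline; ``texture_grain``
    is the ring frequency of the intra-cytoplasm texture (cycles across
    the image).
    """

    name: str
    nucleus_radius_range: tuple
    cytoplasm_radius_range: tuple
    boundary_irregularity: float
    nucleus_intensity: float
    cytoplasm_intensity: float
    texture_grain: float

    def validate(self) -> None:
        for fname in ("nucleus_radius_range", "cytoplasm_radius_range"):
            lo, hi = getattr(self, fname)
            if not (0 < lo <= hi < 0.5):
                raise ValueError(f"{fname} must satisfy 0 < lo <= hi < 0.5, got {(lo, hi)}")
        if self.nucleus_radius_range[1] >= self.cytoplasm_radius_range[0]:
            raise ValueError(
                "nucleus_radius_range max must be < cytoplasm_radius_range min "
                f"(nucleus inside cytoplasm), got {self.nucleus_radius_range} "
                f"vs {self.cytoplasm_radius_range}")
        if not 0 <= self.boundary_irregularity < 1:
            raise ValueError(f"boundary_irregularity must be in [0, 1), "
                             f"got {self.boundary_irregularity}")
        for fname in ("nucleus_intensity", "cytoplasm_intensity"):
            v = getattr(self, fname)
            if not 0 <= v <= 1:
                raise ValueError(f"{fname} must be in [0, 1], got {v}")
        if self.texture_grain < 0:
            raise ValueError(f"texture_grain must be >= 0, got {self.texture_grain}")

    @property
    def nc_ratio(self) -> float:
        """Mid-range nucleus/cytoplasm radius ratio."""
        return (sum(self.nucleus_radius_range) / 2) / (sum(self.cytoplasm_radius_range) / 2)


def default_classes() -> list:
    """Five classes ordered by increasing N/C ratio, loosely patterned on
    the superficial-intermediate -> dyskeratotic gradient of cervical
    cytology (large pale cytoplasm with a pyknotic nucleus at one end,
    a dominant dark nucleus at the other)."""
    return [
        ClassMorphology("superficial_like", (0.04, 0.06), (0.38, 0.44),
                        0.08, 0.25, 0.75, 2.0),
        ClassMorphology("parabasal_like", (0.09, 0.11), (0.30, 0.34),
                        0.03, 0.20, 0.60, 3.0),
        ClassMorphology("metaplastic_like", (0.12, 0.14), (0.30, 0.34),
                        0.05, 0.30, 0.55, 5.0),
        ClassMorphology("koilocytotic_like", (0.14, 0.17), (0.30, 0.34),
                        0.12, 0.35, 0.65, 7.0),
        ClassMorphology("dyskeratotic_like", (0.18, 0.22), (0.28, 0.32),
                        0.15, 0.15, 0.45, 9.0),
    ]


@dataclass
class SyntheticSpec:
    """Full specification of a synthetic dataset."""

    image_size: int = 64
    classes: list = field(default_factory=default_classes)
    noise_sd: float = 0.03
    background_level: float = 0.85

    def validate(self) -> None:
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")
        if not 2 <= len(self.classes) <= 10:
            raise ValueError(f"need 2-10 classes, got {len(self.classes)}")
        if not 0 <= self.noise_sd <= 1:
            raise ValueError(f"noise_sd must be in [0, 1], got {self.noise_sd}")
        if not 0 <= self.background_level <= 1:
            raise ValueError(f"background_level must be in [0, 1], got {self.background_level}")
        for morph in self.classes:
            morph.validate()

    @property
    def class_names(self) -> list:
        return [m.name for m in self.classes]


def render_cell(class_morph: ClassMorphology, rng_seed: int,
                image_size: int = 64, noise_sd: float = 0.03,
                background_level: float = 0.85, center=None,
                return_meta: bool = False):
    """Render one cell: a perturbed-ellipse cytoplasm with an interior
    nucleus disk, ring texture, and clipped Gaussian intensity noise.

    Returns an (H, W, 3) float array in [0, 1] (grayscale replicated to
    3 channels so synthetic and real RGB pipelines share one code path).
    With ``return_meta=True`` also returns the sampled radii/center.
    """
    class_morph.validate()
    if image_size < 16:
        raise ValueError(f"image_size must be >= 16, got {image_size}")
    rng = np.random.default_rng(rng_seed)
    s = image_size
    r_c = rng.uniform(*class_morph.cytoplasm_radius_range) * s
    r_n = rng.uniform(*class_morph.nucleus_radius_range) * s
    if center is None:
        cx = rng.uniform(0.46, 0.54) * (s - 1)
        cy = rng.uniform(0.46, 0.54) * (s - 1)
    else:
        cx, cy = (center[0] * (s - 1), center[1] * (s - 1))
    # boundary perturbation: low-order harmonics, amplitudes normalized so
    # the total relative deviation stays within +/- boundary_irregularity
    amps = rng.uniform(0.2, 1.0, size=len(_BOUNDARY_HARMONICS))
    amps = amps / amps.sum() * class_morph.boundary_irregularity
    phases = rng.uniform(0, 2 * np.pi, size=len(_BOUNDARY_HARMONICS))

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    radius = r_c * (1.0 + sum(a * np.cos(k * theta + p)
                              for a, k, p in zip(amps, _BOUNDARY_HARMONICS, phases)))

    img = np.full((s, s), background_level, dtype=np.float64)
    cyto = dist <= radius
    texture = _TEXTURE_AMPLITUDE * np.cos(2 * np.pi * class_morph.texture_grain * dist / s)
    img[cyto] = class_morph.cytoplasm_intensity + texture[cyto]
    nucleus = dist <= r_n
    img[nucleus] = class_morph.nucleus_intensity
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=(s, s))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    out = np.repeat(img[:, :, None], 3, axis=2)
    if return_meta:
        return out, {"r_nucleus": r_n, "r_cytoplasm": r_c, "center": (cx, cy)}
    return out


def generate_dataset(spec: SyntheticSpec, n_per_class: int, seed: int) -> LabeledImageSet:
    """Generate ``n_per_class`` images for every class in ``spec``.

    Per-image seeds are drawn from a generator seeded with ``seed``, so
    the whole dataset is a pure function of (spec, n_per_class, seed).
    """
    spec.validate()
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=len(spec.classes) * n_per_class)
    items, meta = [], []
    k = 0
    for ci, morph in enumerate(spec.classes):
        for _ in range(n_per_class):
            img = render_cell(morph, int(seeds[k]), spec.image_size,
                              spec.noise_sd, spec.background_level)
            items.append((img, ci))
            meta.append({"seed": int(seeds[k])})
            k += 1
    return LabeledImageSet(items=items, class_names=spec.class_names, item_meta=meta)


def write_image_folder(dataset: LabeledImageSet, out_dir) -> Path:
    """Write a dataset as PNGs in the one-subdirectory-per-class layout
    plus a ``manifest.csv`` (filename, class_name, class_index, seed)."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_class_counter = {}
    rows = []
    for i, (img, ci) in enumerate(dataset.items):
        cname = dataset.class_names[ci]
        cdir = out_dir / cname
        cdir.mkdir(exist_ok=True)
        j = per_class_counter.get(ci, 0)
        per_class_counter[ci] = j + 1
        fname = f"{cname}_{j:04d}.png"
        arr = dataset.load_array(i)
        Image.fromarray((arr * 255).round().astype(np.uint8)).save(cdir / fname)
        seed = dataset.item_meta[i].get("seed", "") if dataset.item_meta else ""
        rows.append((f"{cname}/{fname}", cname, ci, seed))
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "class_name", "class_index", "seed"])
        writer.writerows(rows)
    return out_dir
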