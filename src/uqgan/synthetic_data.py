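"""Seeded long-tailed phantom datasets for segmentation and classification.

The generator emulates the statistical structure of abdominal-CT style
benchmarks at desk scale: a dominant background, one large elliptical
"organ" per image, and zero to a few small "lesion" blobs inside the organ,
with per-class Gaussian intensities plus smooth low-frequency texture.
Class-pixel ratios are enforced *pooled over the dataset*, not per image:
at tail ratios like 1:1400 a lesion cannot appear in every small image, so
per-image lesion budgets are allocated adaptively against the running pooled
deficit while sizes and positions stay stochastic.

Determinism: one master seed; each image draws from its own counter-derived
stream, so generating more images never reshuffles earlier ones, and image
``i`` depends only on images ``< i`` (through the pooled deficit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, zoom
from skimage.draw import ellipse as _ellipse

__all__ = [
    "ImbalanceSpec",
    "ShiftSpec",
    "ImageSample",
    "InfeasibleSpecError",
    "lits_like_spec",
    "chaos_like_spec",
    "desk_spec",
    "generate_segmentation_dataset",
    "generate_classification_dataset",
    "apply_domain_shift",
    "pooled_class_fractions",
]


class InfeasibleSpecError(ValueError):
    """Raised when a class's target ratio cannot be realised geometrically."""


@dataclass(frozen=True)
class ImbalanceSpec:
    """Target composition of a long-tailed segmentation phantom dataset.

    ``target_ratios`` are per-class pixel fractions (class 0 = background,
    must dominate); ``intensity_model`` gives per-class (mean, std) of pixel
    intensity in [0, 1]; ``lesion_size_range`` bounds the equivalent
    diameter (pixels) of tail-class blobs.
    """

    class_names: tuple[str, ...] = ("background", "organ", "lesion")
    target_ratios: tuple[float, ...] = (0.90, 0.091, 0.009)
    image_size: tuple[int, int] = (64, 64)
    intensity_model: tuple[tuple[float, float], ...] = (
        (0.25, 0.06), (0.55, 0.06), (0.85, 0.06))
    lesion_size_range: tuple[float, float] = (3.0, 9.0)
    texture_std: float = 0.03
    max_lesions_per_image: int = 3

    def __post_init__(self):
        r = np.asarray(self.target_ratios, dtype=float)
        if len(self.class_names) != len(r) or len(r) != len(self.intensity_model):
            raise ValueError("class_names, target_ratios, intensity_model "
                             "must have equal length")
        if np.any(r <= 0):
            raise ValueError("target_ratios must be strictly positive")
        if not np.isclose(r.sum(), 1.0, atol=1e-8):
            raise ValueError(f"target_ratios must sum to 1 (got {r.sum():.6f})")
        if r[0] < r.max():
            raise ValueError("class 0 (background) must have the largest fraction")
        lo, hi = self.lesion_size_range
        if lo < 1:
            raise ValueError("lesion_size_range min must be >= 1 pixel")
        if hi >= min(self.image_size):
            raise ValueError("lesion_size_range max must be < min(image_size)")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass(frozen=True)
class ShiftSpec:
    """Acquisition-shift transform emulating a different scanner/population."""

    intensity_offset: float = 0.15
    contrast_scale: float = 1.2
    texture_noise_std: float = 0.05
    resolution_factor: float = 1.0

    def __post_init__(self):
        if not -1.0 <= self.intensity_offset <= 1.0:
            raise ValueError("intensity_offset must be in [-1, 1]")
        if self.contrast_scale <= 0:
            raise ValueError("contrast_scale must be > 0")
        if self.texture_noise_std < 0:
            raise ValueError("texture_noise_std must be >= 0")
        if self.resolution_factor <= 0:
            raise ValueError("resolution_factor must be > 0")

    @property
    def is_identity(self) -> bool:
        return (self.intensity_offset == 0.0 and self.contrast_scale == 1.0
                and self.texture_noise_std == 0.0 and self.resolution_factor == 1.0)


IDENTITY_SHIFT = ShiftSpec(0.0, 1.0, 0.0, 1.0)


@dataclass
class ImageSample:
    """An image with its pixel mask (segmentation) or class label."""

    image: np.ndarray
    mask: np.ndarray | None = None
    label: int | None = None
    sample_id: str = ""
    domain_tag: str = "in-distribution"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mask is not None and self.image.shape[-2:] != self.mask.shape:
            raise ValueError("image and mask must share spatial dimensions")


def lits_like_spec(image_size: tuple[int, int] = (64, 64)) -> ImbalanceSpec:
    """Liver-tumour style composition: organ 1:400, lesion 1:1400 vs background.

    With background fraction b, organ = b/400 and lesion = b/1400.
    """
    b = 1.0 / (1.0 + 1.0 / 400.0 + 1.0 / 1400.0)
    return ImbalanceSpec(
        class_names=("background", "organ", "lesion"),
        target_ratios=(b, b / 400.0, b / 1400.0),
        image_size=image_size,
        lesion_size_range=(1.5, 4.0),
    )


def chaos_like_spec(image_size: tuple[int, int] = (64, 64)) -> ImbalanceSpec:
    """Multi-organ style composition with ratios 1:40, 1:200, 1:400, 1:400."""
    inv = np.array([1 / 40, 1 / 200, 1 / 400, 1 / 400])
    b = 1.0 / (1.0 + inv.sum())
    return ImbalanceSpec(
        class_names=("background", "organ_a", "organ_b", "organ_c", "organ_d"),
        target_ratios=(b, *(b * inv)),
        image_size=image_size,
        intensity_model=((0.2, 0.06), (0.5, 0.06), (0.65, 0.06),
                         (0.8, 0.06), (0.9, 0.06)),
        lesion_size_range=(2.0, 6.0),
    )


def desk_spec(image_size: tuple[int, int] = (64, 64)) -> ImbalanceSpec:
    """Desk-scale default: organ head class, lesion tail at 1:100 vs background."""
    return ImbalanceSpec(image_size=image_size)


def _img_rng(seed: int, index: int, purpose: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, purpose, index])


def generate_segmentation_dataset(spec: ImbalanceSpec, n_images: int,
                                  seed: int) -> list[ImageSample]:
    """Generate ``n_images`` phantom image/mask pairs matching ``spec``.

    Pooled per-class pixel fractions over the dataset track ``target_ratios``
    (within ±20% relative at n around 200, tightening as n grows); every
    image contains background.  Deterministic for a fixed seed, and image
    ``i`` is unchanged when ``n_images`` increases.
    """
    if n_images < 0:
        raise ValueError("n_images must be >= 0")
    h, w = spec.image_size
    area = h * w
    ratios = np.asarray(spec.target_ratios, dtype=float)
    # feasibility: each non-background class's per-image pixel budget must be
    # attainable with at most max_lesions_per_image blobs of the largest size
    # (class 1 is the organ and may be a large ellipse instead)
    lo, hi = spec.lesion_size_range
    max_blob_area = np.pi * (hi / 2.0) ** 2
    for c in range(2, spec.n_classes):
        need = ratios[c] * area
        if need > spec.max_lesions_per_image * max_blob_area:
            raise InfeasibleSpecError(
                f"class {spec.class_names[c]!r}: target ratio {ratios[c]:.4g} "
                f"requires {need:.0f} px/image but at most "
                f"{spec.max_lesions_per_image} blobs of diameter {hi} fit "
                f"({spec.max_lesions_per_image * max_blob_area:.0f} px)")
    if ratios[1] * area > 0.5 * area and spec.n_classes > 1:
        raise InfeasibleSpecError(
            f"class {spec.class_names[1]!r}: organ fraction {ratios[1]:.3f} "
            "too large for the background-dominant phantom geometry")

    samples: list[ImageSample] = []
    placed = np.zeros(spec.n_classes)  # pooled pixel counts so far
    mean_blob = np.pi * ((lo + hi) / 4.0) ** 2
    for i in range(n_images):
        rng = _img_rng(seed, i, purpose=1)
        mask = np.zeros((h, w), dtype=np.int64)
        # organ: one ellipse, area jittered around the per-image target,
        # nudged by the pooled deficit so the dataset composition converges
        if spec.n_classes >= 2:
            target_cum = ratios[1] * area * (i + 1)
            deficit = target_cum - placed[1]
            organ_area = max(4.0, deficit * rng.uniform(0.8, 1.2))
            organ_area = min(organ_area, 0.6 * area)
            ecc = rng.uniform(0.6, 1.0)
            r_a = np.sqrt(organ_area / (np.pi * ecc))
            r_b = r_a * ecc
            cy = rng.uniform(0.3 * h, 0.7 * h)
            cx = rng.uniform(0.3 * w, 0.7 * w)
            ang = rng.uniform(0, np.pi)
            rr, cc = _ellipse(cy, cx, r_a, r_b, shape=(h, w), rotation=ang)
            mask[rr, cc] = 1
        # tail blobs: count chosen against the pooled deficit, sizes random
        organ_px = np.flatnonzero(mask.ravel() == 1)
        for c in range(2, spec.n_classes):
            target_cum = ratios[c] * area * (i + 1)
            deficit = target_cum - placed[c]
            k = int(np.clip(np.floor(deficit / mean_blob + rng.uniform(0, 1)),
                            0, spec.max_lesions_per_image))
            for _ in range(k):
                d = rng.uniform(lo, hi)
                r = d / 2.0
                if organ_px.size:  # lesions sit inside the organ when possible
                    pos = organ_px[rng.integers(organ_px.size)]
                    py, px = divmod(pos, w)
                else:
                    py = rng.uniform(0.2 * h, 0.8 * h)
                    px = rng.uniform(0.2 * w, 0.8 * w)
                rr, cc = _ellipse(py, px, max(r, 0.8), max(r, 0.8), shape=(h, w))
                mask[rr, cc] = c
        counts = np.bincount(mask.ravel(), minlength=spec.n_classes)
        placed += counts
        img = np.zeros((h, w))
        for c, (mu, sd) in enumerate(spec.intensity_model):
            sel = mask == c
            img[sel] = rng.normal(mu, sd, size=int(sel.sum()))
        if spec.texture_std > 0:
            img += gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 4.0) \
                * spec.texture_std * 8.0
        img = np.clip(img, 0.0, 1.0)
        samples.append(ImageSample(image=img, mask=mask,
                                   sample_id=f"seg-{seed}-{i:05d}",
                                   domain_tag="in-distribution",
                                   meta={"seed": seed, "index": i}))
    return samples


def generate_classification_dataset(n_majority: int, n_minority: int,
                                    seed: int,
                                    image_size: tuple[int, int] = (64, 64)
                                    ) -> list[ImageSample]:
    """Binary classification phantoms with a learnable minority signature.

    Majority images (label 0) are smooth textured fields; minority images
    (label 1) additionally carry a faint ring structure.  Labels are
    interleaved deterministically per seed.
    """
    if n_majority < 0 or n_minority < 0:
        raise ValueError("counts must be >= 0")
    h, w = image_size
    n = n_majority + n_minority
    order_rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 2, 0])
    labels = np.array([0] * n_majority + [1] * n_minority)
    order_rng.shuffle(labels)
    single_class = (n_minority == 0 or n_majority == 0) and n > 0
    if single_class:
        warnings.warn("classification dataset contains a single class",
                      UserWarning, stacklevel=2)
    yy, xx = np.mgrid[0:h, 0:w]
    samples = []
    for i in range(n):
        rng = _img_rng(seed, i, purpose=3)
        img = 0.45 + gaussian_filter(rng.normal(0, 1, size=(h, w)), 4.0) * 0.3
        lab = int(labels[i])
        if lab == 1:
            cy = rng.uniform(0.35 * h, 0.65 * h)
            cx = rng.uniform(0.35 * w, 0.65 * w)
            rad = rng.uniform(0.15, 0.3) * min(h, w)
            dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            ring = np.exp(-0.5 * ((dist - rad) / 1.5) ** 2)
            img = img + 0.15 * ring
        img = np.clip(img, 0, 1)
        samples.append(ImageSample(
            image=img, label=lab, sample_id=f"cls-{seed}-{i:05d}",
            domain_tag="in-distribution",
            meta={"seed": seed, "index": i, "single_class": single_class}))
    return samples


def apply_domain_shift(samples: list[ImageSample], shift: ShiftSpec,
                       seed: int) -> list[ImageSample]:
    """Produce the domain-shifted (OOD) variant of a batch.

    Masks and labels are never altered.  The identity shift returns pixel
    data bit-identical to the inputs.  Intensities falling outside [0, 1]
    are clipped and counted; a batch clipping >50% of pixels triggers a
    warning.
    """
    if not samples:
        raise ValueError("samples must be non-empty")
    out = []
    clipped = 0
    total = 0
    for i, s in enumerate(samples):
        if shift.is_identity:
            img = s.image.copy()
        else:
            rng = _img_rng(seed, i, purpose=4)
            img = (s.image - 0.5) * shift.contrast_scale + 0.5
            img = img + shift.intensity_offset
            if shift.texture_noise_std > 0:
                img = img + rng.normal(0.0, shift.texture_noise_std,
                                       size=img.shape)
            if shift.resolution_factor != 1.0:
                f = shift.resolution_factor
                small = zoom(img, 1.0 / f, order=1)
                img = zoom(small, np.array(s.image.shape[-2:], dtype=float)
                           / np.array(small.shape[-2:], dtype=float), order=1)
                img = img[:s.image.shape[-2], :s.image.shape[-1]]
            clipped += int(np.sum((img < 0) | (img > 1)))
            total += img.size
            img = np.clip(img, 0.0, 1.0)
        out.append(ImageSample(
            image=img,
            mask=None if s.mask is None else s.mask.copy(),
            label=s.label,
            sample_id=s.sample_id + "-ood",
            domain_tag="ood",
            meta={**s.meta, "shift": shift, "clipped_fraction":
                  (clipped / total if total else 0.0)}))
    if total and clipped / total > 0.5:
        warnings.warn(f"domain shift clipped {100 * clipped / total:.1f}% "
                      "of pixels", UserWarning, stacklevel=2)
    return out


def pooled_class_fractions(samples: list[ImageSample],
                           n_classes: int | None = None) -> np.ndarray:
    """Empirical pooled per-class pixel fractions over a segmentation dataset."""
    if not samples:
        raise ValueError("samples must be non-empty")
    if n_classes is None:
        n_classes = max(int(s.mask.max()) for s in samples) + 1
    counts = np.zeros(n_classes)
    for s in samples:
        counts += np.bincount(s.mask.ravel(), minlength=n_classes)
    return counts / counts.sum()
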