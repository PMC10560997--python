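"""Disk formats: PNG image/mask pairs, CSV manifests, checkpoints, reports.

Images are written as 8-bit grayscale PNG, masks as single-channel integer
PNG (the label *is* the pixel value; palette PNGs are rejected).  A CSV
manifest ties a dataset together.  Optional NIfTI export stacks a dataset
into a pseudo-volume.  Parameter checkpoints are single-file ``.npz``
containers with a version field.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .networks import GeneratorSpec, NetworkParameters
from .synthetic_data import ImageSample

__all__ = [
    "write_dataset",
    "read_dataset",
    "export_nifti",
    "save_checkpoint",
    "load_checkpoint",
    "write_uncertainty_map",
]

CHECKPOINT_VERSION = 1


def write_dataset(samples: list[ImageSample], outdir: str | Path,
                  force: bool = False) -> Path:
    """Write image/mask PNG pairs and a manifest.csv; returns the manifest path."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.csv"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists (use force=True/--force)")
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    has_masks = any(s.mask is not None for s in samples)
    if has_masks:
        (outdir / "masks").mkdir(exist_ok=True)
    for s in samples:
        img8 = np.clip(np.round(s.image * 255.0), 0, 255).astype(np.uint8)
        img_rel = f"images/{s.sample_id}.png"
        iio.imwrite(outdir / img_rel, img8)
        mask_rel = ""
        if s.mask is not None:
            if s.mask.max() > 255:
                raise ValueError("masks with >255 classes are not supported")
            mask_rel = f"masks/{s.sample_id}.png"
            iio.imwrite(outdir / mask_rel, s.mask.astype(np.uint8))
        rows.append({"sample_id": s.sample_id, "image": img_rel,
                     "mask": mask_rel,
                     "label": -1 if s.label is None else int(s.label),
                     "domain_tag": s.domain_tag})
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


def read_dataset(manifest_path: str | Path) -> list[ImageSample]:
    """Load a dataset written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path, keep_default_na=False)
    samples = []
    for row in df.itertuples(index=False):
        img = iio.imread(root / row.image)
        if img.ndim == 3 and img.shape[-1] in (3, 4):  # palette/RGB guard
            raise ValueError(
                f"{row.image}: expected single-channel PNG, got shape {img.shape}"
                " — palette or RGB masks/images are not supported")
        image = img.astype(np.float64) / 255.0
        mask = None
        if row.mask:
            m = iio.imread(root / row.mask)
            if m.ndim != 2:
                raise ValueError(f"{row.mask}: masks must be single-channel "
                                 "integer PNGs (palette PNGs are rejected)")
            mask = m.astype(np.int64)
        label = None if int(row.label) < 0 else int(row.label)
        samples.append(ImageSample(image=image, mask=mask, label=label,
                                   sample_id=str(row.sample_id),
                                   domain_tag=str(row.domain_tag)))
    return samples


def export_nifti(samples: list[ImageSample], path: str | Path,
                 spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Path:
    """Stack a dataset's images into a float32 pseudo-volume (.nii.gz)."""
    import nibabel as nib
    vol = np.stack([s.image for s in samples]).astype(np.float32)
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(np.moveaxis(vol, 0, -1), affine)
    path = Path(path)
    nib.save(img, str(path))
    return path


def save_checkpoint(path: str | Path, params: NetworkParameters,
                    generator_spec: GeneratorSpec, extra: dict | None = None
                    ) -> Path:
    """Single-file parameter container with version + architecture metadata."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    meta = {"version": CHECKPOINT_VERSION,
            "generator_spec": generator_spec.__dict__,
            "n_arrays": params.d, **(extra or {})}
    arrays = {f"theta_{i:04d}": a for i, a in enumerate(params.theta)}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path) -> tuple[NetworkParameters, GeneratorSpec, dict]:
    """Load a checkpoint; raises on version or architecture mismatch."""
    with np.load(path) as zf:
        meta = json.loads(bytes(zf["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {meta.get('version')} != "
                f"{CHECKPOINT_VERSION}; refusing to load")
        theta = [zf[f"theta_{i:04d}"] for i in range(meta["n_arrays"])]
    spec = GeneratorSpec(**meta["generator_spec"])
    return NetworkParameters(theta), spec, meta


def write_uncertainty_map(path: str | Path, total_variance: np.ndarray) -> Path:
    """16-bit PNG of a per-pixel variance field, scale in a sidecar JSON."""
    path = Path(path)
    vmax = float(total_variance.max()) or 1.0
    scaled = np.round(total_variance / vmax * 65535.0).astype(np.uint16)
    iio.imwrite(path, scaled)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"scale": vmax / 65535.0, "units":
                                   "total predictive variance"}))
    return path
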