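"""Synthetic fixtures: texture images and tabular datasets.

The image generator produces Gaussian-random-field textures — seeded white
noise smoothed at a class-specific correlation length, scaled by a
class-specific contrast around a base intensity and quantized to 8 bits.
Such fields have exactly the second-order statistics (co-occurrence,
run-length, local binary patterns) the descriptor stack measures, so eight
classes with distinct generative parameters are separable by the pipeline
while remaining download-free.  The default class counts reproduce the
canonical INbreast BI-RADS distribution 67/220/24/13/8/21/50/8 (411 images).

The tabular generator is a desk-scale surrogate for the 88-feature table:
``n_informative`` features are class-mean-shifted Gaussians (hypercube-
corner means scaled by ``class_sep``) and ``n_noise`` features are
label-independent standard normals.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .adasyn import LabeledDataset

#: BI-RADS class sizes 1..8 (the published 411-image distribution).
TABLE1_COUNTS = (67, 220, 24, 13, 8, 21, 50, 8)


@dataclass(frozen=True)
class TextureClassSpec:
    label: int
    correlation_length: float  # Gaussian-blur sigma of the random field, px
    contrast: float            # intensity spread (std of the scaled field)
    base_level: float          # mean intensity, 0..255
    n_images: int

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.correlation_length <= 0 or self.contrast <= 0:
            raise ValueError("correlation_length and contrast must be positive")


@dataclass
class FixtureManifest:
    """Images (in memory and/or on disk) with labels and provenance."""

    images: list[np.ndarray]
    labels: np.ndarray
    paths: list[str]
    specs: tuple[TextureClassSpec, ...]
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"path": self.paths, "label": self.labels,
             "sha256": [hashlib.sha256(im.tobytes()).hexdigest() for im in self.images]}
        )


def default_texture_specs(
    counts: tuple[int, ...] = TABLE1_COUNTS
) -> tuple[TextureClassSpec, ...]:
    """Eight texture classes with distinct smoothness/contrast/brightness."""
    corr = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)
    contrast = (55, 50, 45, 40, 38, 35, 32, 30)
    base = (90, 100, 110, 120, 130, 140, 150, 160)
    return tuple(
        TextureClassSpec(i + 1, corr[i], contrast[i], base[i], counts[i])
        for i in range(8)
    )


def gaussian_field(
    size: int, correlation_length: float, contrast: float, base_level: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One 8-bit Gaussian-random-field texture image."""
    noise = rng.normal(size=(size, size))
    field = gaussian_filter(noise, sigma=correlation_length, mode="wrap")
    sd = field.std()
    if sd > 0:
        field = field / sd
    img = base_level + contrast * field
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def make_texture_dataset(
    specs: tuple[TextureClassSpec, ...] | None = None,
    size: int = 64,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> FixtureManifest:
    """Generate the labeled texture-image fixture set.

    With ``out_dir`` set, PNGs and a ``manifest.csv`` are written there;
    otherwise images stay in memory.  Byte-identical for a fixed seed.
    """
    if specs is None:
        specs = default_texture_specs()
    if size < 32:
        raise ValueError("size must be >= 32")
    images: list[np.ndarray] = []
    labels: list[int] = []
    paths: list[str] = []
    for spec in specs:
        rng = np.random.default_rng([seed, spec.label])
        for i in range(spec.n_images):
            img = gaussian_field(
                size, spec.correlation_length, spec.contrast, spec.base_level, rng
            )
            images.append(img)
            labels.append(spec.label)
            paths.append(f"class{spec.label}_{i:04d}.png")
    manifest = FixtureManifest(images, np.array(labels), paths, tuple(specs), seed)
    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, rel in zip(manifest.images, manifest.paths):
            iio.imwrite(out / rel, img)
        manifest.paths = [str(out / rel) for rel in manifest.paths]
        manifest.frame().to_csv(out / "manifest.csv", index=False)
    return manifest


def make_tabular_dataset(
    n_per_class: tuple[int, ...] = TABLE1_COUNTS,
    n_informative: int = 10,
    n_noise: int = 78,
    class_sep: float = 4.0,
    seed: int = 0,
) -> LabeledDataset:
    """Labeled Gaussian tabular dataset with nested informative features.

    Class c's informative features are centered at class_sep/2 times a
    distinct random +-1 hypercube corner; noise features are N(0, 1)
    independent of the label.  Labels are 1-based (BI-RADS style).
    """
    if any(c < 1 for c in n_per_class):
        raise ValueError("all class counts must be >= 1")
    n_classes = len(n_per_class)
    rng = np.random.default_rng(seed)
    # distinct sign patterns per class
    corners: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    while len(corners) < n_classes:
        c = tuple(int(s) for s in rng.choice([-1, 1], size=n_informative))
        if c not in seen:
            seen.add(c)
            corners.append(c)
    X_parts, y_parts = [], []
    for label0, count in enumerate(n_per_class):
        mean = np.array(corners[label0], dtype=float) * class_sep / 2.0
        informative = rng.normal(size=(count, n_informative)) + mean
        noise = rng.normal(size=(count, n_noise))
        X_parts.append(np.hstack([informative, noise]))
        y_parts.append(np.full(count, label0 + 1))
    names = tuple(
        [f"informative_{i}" for i in range(n_informative)]
        + [f"noise_{i}" for i in range(n_noise)]
    )
    return LabeledDataset(np.vstack(X_parts), np.concatenate(y_parts), names)


def write_dicom(path: str | Path, pixels: np.ndarray) -> None:
    """Write a minimal synthetic secondary-capture DICOM for one 8-bit image.

    Test/fixture plumbing: a stand-in exercising the DICOM reading path, not
    a clinical file.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    pixels = np.asarray(pixels, dtype=np.uint8)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid(
        entropy_srcs=[str(path)]
    )
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
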