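"""Image and feature-table I/O, pipeline configuration, seed fan-out."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adasyn import AdasynConfig, LabeledDataset
from .network import TrainConfig
from .relieff import ReliefFConfig
from .textures import FeatureConfig, GrayImage

logger = logging.getLogger("mammotex")

LABEL_COLUMN = "label"
SOURCE_COLUMN = "source"
SYNTHETIC_COLUMN = "synthetic"
_RESERVED = (LABEL_COLUMN, SOURCE_COLUMN, SYNTHETIC_COLUMN)


def read_image(path: str | Path) -> GrayImage:
    """Read a single-channel image from DICOM, PNG or TIFF.

    Multi-channel input is collapsed to luminance by channel averaging (with
    a warning); bit depth is taken from the file metadata so 16-bit input
    quantizes consistently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".dcm", ".dicom"):
            import pydicom

            ds = pydicom.dcmread(path)
            arr = ds.pixel_array
            n_levels = 2 ** int(ds.BitsStored)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
            n_levels = 65536 if arr.dtype == np.uint16 else 256
    except Exception as exc:  # pragma: no cover - message formatting
        raise ValueError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3:
        logger.warning("%s is multi-channel; averaging channels to luminance", path)
        arr = arr.mean(axis=2)
    return GrayImage(np.round(arr).astype(np.int64), n_levels)


def write_feature_table(dataset: LabeledDataset, path: str | Path,
                        sources: list[str] | None = None) -> None:
    """Write one row per image: named features + label (+ provenance)."""
    names = dataset.feature_names or tuple(
        f"f{i}" for i in range(dataset.n_features)
    )
    df = pd.DataFrame(dataset.X, columns=list(names))
    df[LABEL_COLUMN] = dataset.y
    if sources is not None:
        df[SOURCE_COLUMN] = sources
    if dataset.synthetic is not None and dataset.synthetic.any():
        df[SYNTHETIC_COLUMN] = dataset.synthetic
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> LabeledDataset:
    df = pd.read_csv(path)
    if LABEL_COLUMN not in df.columns:
        raise ValueError(f"{path} has no '{LABEL_COLUMN}' column")
    feature_cols = [c for c in df.columns if c not in _RESERVED]
    synthetic = (
        df[SYNTHETIC_COLUMN].to_numpy(dtype=bool)
        if SYNTHETIC_COLUMN in df.columns
        else None
    )
    return LabeledDataset(
        df[feature_cols].to_numpy(dtype=float),
        df[LABEL_COLUMN].to_numpy(),
        tuple(feature_cols),
        synthetic,
    )


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: first 4 bytes of sha256("seed/stage")."""
    digest = hashlib.sha256(f"{global_seed}/{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _from_mapping(cls, data: dict):
    """Build a (frozen) dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration (single global seed fans out per stage)."""

    seed: int = 0
    image_dir: str | None = None     # directory with manifest.csv, or None to
    image_size: int = 64             # generate the synthetic fixture set
    features: FeatureConfig = field(default_factory=FeatureConfig)
    adasyn: AdasynConfig = field(default_factory=AdasynConfig)
    relieff: ReliefFConfig = field(default_factory=ReliefFConfig)
    hidden: tuple[int, ...] = (40, 20, 10)
    layer1_linear: bool = False
    train: TrainConfig = field(default_factory=TrainConfig)
    oversample_enabled: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sub = {
            "features": FeatureConfig,
            "adasyn": AdasynConfig,
            "relieff": ReliefFConfig,
            "train": TrainConfig,
        }
        parsed = {}
        for key, subcls in sub.items():
            if key in data:
                parsed[key] = _from_mapping(subcls, data.pop(key) or {})
        cfg = _from_mapping(cls, data)
        for key, value in parsed.items():
            object.__setattr__(cfg, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        import json

        # json round-trip turns tuples into plain lists for safe_dump
        data = json.loads(json.dumps(asdict(self)))
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, default_flow_style=False)
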