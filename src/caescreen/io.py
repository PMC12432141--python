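"""File formats: 16-bit grayscale TIFF images, CSV manifests, YAML configs."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .cae import CAEConfig
from .errors import FormatError, ValidationError
from .scoring import IRE_PERCENTILE, THRESHOLD_MULTIPLIER

MANIFEST_LABELS = {"clean", "artifact", "unknown"}


def read_image(path: str | Path, bit_depth: int = 14,
               allow_high: bool = False) -> np.ndarray:
    """Read a single-channel integer image (TIFF, or 16-bit PNG).

    Values above 2^bit_depth - 1 are rejected unless ``allow_high`` is set,
    catching images from a different sensor configuration early.
    """
    path = Path(path)
    try:
        if path.suffix.lower() == ".png":
            import imageio.v3 as iio
            img = iio.imread(path)
        else:
            img = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed container
        raise FormatError(f"{path}: could not read image ({exc})") from exc
    if img.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-channel image, got shape {img.shape}"
        )
    if not np.issubdtype(img.dtype, np.integer):
        raise FormatError(f"{path}: expected integer pixels, got dtype {img.dtype}")
    full = 2**bit_depth - 1
    mx = int(img.max()) if img.size else 0
    if not allow_high and mx > full:
        raise ValidationError(
            f"{path}: max intensity {mx} exceeds {bit_depth}-bit full scale {full}"
        )
    if int(img.min()) < 0:
        raise ValidationError(f"{path}: negative intensities present")
    return np.asarray(img, dtype=np.uint16)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a 2-D non-negative integer image as 16-bit grayscale TIFF."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer) or arr.min() < 0 or arr.max() > 65535:
        raise ValidationError("image must be non-negative integers <= 65535")
    tifffile.imwrite(Path(path), arr.astype(np.uint16))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load a ``path,label[,seed]`` manifest CSV.

    Paths are kept as written plus a resolved ``abspath`` column (relative
    paths resolve against the manifest's directory). Labels must come from
    the closed vocabulary {clean, artifact, unknown}; a missing label column
    is filled with ``unknown``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "path" not in df.columns:
        raise FormatError(f"{path}: manifest needs a 'path' column")
    if "label" not in df.columns:
        df["label"] = "unknown"
    df["label"] = df["label"].fillna("unknown")
    bad = set(df["label"]) - MANIFEST_LABELS
    if bad:
        raise ValidationError(f"{path}: labels outside {sorted(MANIFEST_LABELS)}: {sorted(bad)}")
    if df["path"].duplicated().any():
        dups = df.loc[df["path"].duplicated(), "path"].tolist()
        raise ValidationError(f"{path}: duplicate image paths {dups}")
    base = path.parent
    df["abspath"] = [str((base / p).resolve()) if not Path(p).is_absolute() else p
                     for p in df["path"]]
    return df


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline, one master seed included.

    Round-trips losslessly through YAML so every report can be traced to
    the exact configuration that produced it.
    """

    seed: int = 0
    # preprocessing
    blur_kernel: int = 5
    blur_sigma: float | None = None
    sd_mult: float = 5.0
    block: int = 2
    bit_depth: int = 14
    # model
    cae: CAEConfig = field(default_factory=CAEConfig)
    # scoring
    ire_percentile: float = IRE_PERCENTILE
    threshold_multiplier: float = THRESHOLD_MULTIPLIER
    fixed_threshold: float | None = None
    # evaluation
    n_subsets: int = 10_000
    # optional simulation stage
    simulate: dict | None = None
    # train/score split: number of clean images used for training
    n_train_clean: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cae"] = self.cae.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cae" in d and isinstance(d["cae"], dict):
            d["cae"] = CAEConfig.from_dict(d["cae"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
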