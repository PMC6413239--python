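"""Raster I/O for micrographs and annotation masks, plus dataset manifests.

Conventions used throughout the package:

* coordinates are ``(row, col)``, 0-based, row 0 at the top;
* micrograph intensities live in ``[0, 1]`` (rescaled from the integer
  range of the file format);
* masks are binary, 1 = polar-body region, and are persisted as 8-bit PNG
  with 0 = background and 255 = foreground;
* image height and width must each be divisible by 16 so that four rounds
  of 2x pooling land on integer sizes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "Micrograph",
    "LabelMask",
    "ManifestEntry",
    "DatasetManifest",
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
    "load_manifest",
    "save_manifest",
]

#: pixels per 10 micrometres at the nominal magnification
DEFAULT_PIXELS_PER_10UM = 16.0

# ITU-R BT.601 luminance weights, used when a camera delivers RGB frames.
_LUMA = np.array([0.299, 0.587, 0.114])


def _check_size(height: int, width: int) -> None:
    for name, dim in (("height", height), ("width", width)):
        if dim < 16:
            raise ValueError(f"{name} must be >= 16 pixels, got {dim}")
        if dim % 16 != 0:
            raise ValueError(
                f"{name} must be divisible by 16 (four 2x poolings), got {dim}"
            )


@dataclass(frozen=True)
class Micrograph:
    """Single-channel intensity image in [0, 1]."""

    pixels: np.ndarray
    pixels_per_10um: float = DEFAULT_PIXELS_PER_10UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"micrograph must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("micrograph contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("micrograph intensities must lie in [0, 1]")
        _check_size(*px.shape)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LabelMask:
    """Binary per-pixel annotation; 1 marks the polar-body region."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {px.shape}")
        vals = np.unique(px)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        _check_size(*px.shape)
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def is_empty(self) -> bool:
        return not bool(self.pixels.any())

    def foreground_centroid(self) -> tuple[float, float] | None:
        """Mean (row, col) of foreground pixels, or None for an empty mask."""
        rr, cc = np.nonzero(self.pixels)
        if rr.size == 0:
            return None
        return float(rr.mean()), float(cc.mean())


@dataclass(frozen=True)
class ManifestEntry:
    image: str
    mask: str | None
    label: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")


@dataclass
class DatasetManifest:
    """Ordered pairing of image and mask files with a presence label.

    Paths are stored relative to ``root`` (the directory the manifest CSV
    lives in) unless absolute.
    """

    entries: list[ManifestEntry] = field(default_factory=list)
    root: Path = Path(".")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ManifestEntry]:
        return iter(self.entries)

    def image_path(self, entry: ManifestEntry) -> Path:
        return self.root / entry.image

    def mask_path(self, entry: ManifestEntry) -> Path | None:
        return None if entry.mask is None else self.root / entry.mask

    def validate_files(self) -> None:
        for e in self.entries:
            if not self.image_path(e).exists():
                raise FileNotFoundError(f"manifest image missing: {self.image_path(e)}")
            mp = self.mask_path(e)
            if mp is not None and not mp.exists():
                raise FileNotFoundError(f"manifest mask missing: {mp}")


def _load_gray(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read a raster, convert RGB(A) to luminance, return (array, format max)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    arr = iio.imread(path)
    if arr.dtype == np.uint16:
        maxval = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        maxval = 1.0
    else:
        maxval = 255.0
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return np.asarray(arr, dtype=np.float64), maxval


def read_image(path: str | os.PathLike, pixels_per_10um: float = DEFAULT_PIXELS_PER_10UM) -> Micrograph:
    """Read a grayscale PNG/TIFF and rescale intensities to [0, 1]."""
    arr, maxval = _load_gray(path)
    return Micrograph(np.clip(arr / maxval, 0.0, 1.0), pixels_per_10um)


def read_mask(path: str | os.PathLike) -> LabelMask:
    """Read an annotation raster; pixels above half the format maximum are 1."""
    arr, maxval = _load_gray(path)
    return LabelMask((arr > maxval / 2.0).astype(np.uint8))


def write_image(m: Micrograph, path: str | os.PathLike) -> None:
    """Write a micrograph as an 8-bit grayscale raster (PNG or TIFF)."""
    _check_writable(path)
    data = np.round(m.pixels * 255.0).astype(np.uint8)
    iio.imwrite(Path(path), data)


def write_mask(l: LabelMask, path: str | os.PathLike) -> None:
    """Write a mask as 8-bit PNG, 0 = background, 255 = polar body."""
    _check_writable(path)
    iio.imwrite(Path(path), (l.pixels * 255).astype(np.uint8))


def _check_writable(path: str | os.PathLike) -> None:
    parent = Path(path).parent
    if not parent.is_dir():
        raise IOError(f"cannot write {path}: directory {parent} does not exist")


def load_manifest(path: str | os.PathLike, check_files: bool = True) -> DatasetManifest:
    """Load a CSV manifest with columns image,mask,label.

    An empty mask cell means the (negative) entry carries no mask file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = {"image", "mask", "label"}
    if not expected.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(expected)}, got {list(df.columns)}")
    entries = [
        ManifestEntry(row.image, row.mask or None, row.label)
        for row in df.itertuples(index=False)
    ]
    manifest = DatasetManifest(entries, root=path.parent)
    if check_files:
        manifest.validate_files()
    return manifest


def save_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    """Write the manifest as CSV, preserving entry order."""
    _check_writable(path)
    df = pd.DataFrame(
        {
            "image": [e.image for e in manifest.entries],
            "mask": [e.mask or "" for e in manifest.entries],
            "label": [e.label for e in manifest.entries],
        }
    )
    df.to_csv(path, index=False)
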