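"""Paired image/mask augmentation: rotation, flipping, elastic deformation.

The elastic deformation follows the random-displacement-field recipe used
for handwriting and biomedical segmentation networks: draw per-pixel
displacements i.i.d. uniform on (-1, 1), smooth each field with a unit-sum
Gaussian kernel of standard deviation ``sigma``, scale by ``alpha``, and
resample the image at the displaced coordinates.  The same field is applied
to an image and its mask so the annotation stays glued to the anatomy.

All transforms accept and return :class:`~polarseg.io.Micrograph` /
:class:`~polarseg.io.LabelMask` pairs; array-level helpers (prefixed with
an underscore) are shared with the synthetic-scene renderer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import (
    DatasetManifest,
    LabelMask,
    ManifestEntry,
    Micrograph,
    read_image,
    read_mask,
    save_manifest,
    write_image,
    write_mask,
)

__all__ = [
    "ElasticParams",
    "DisplacementField",
    "rotate_pair",
    "flip_pair",
    "make_displacement",
    "elastic_pair",
    "augment_manifest",
]

# Gaussian kernel truncated at 4 sigma: < 0.01% of the mass is lost and the
# kernel extent is reproducible.
_TRUNCATE = 4.0


@dataclass(frozen=True)
class ElasticParams:
    """Elastic-deformation parameters: displacement scale alpha (px),
    Gaussian smoothing std sigma (px), and the RNG seed."""

    alpha: float
    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class DisplacementField:
    """Per-pixel sampling offsets: ``dx`` displaces columns, ``dy`` rows."""

    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self) -> None:
        if self.dx.shape != self.dy.shape:
            raise ValueError("dx and dy must share a shape")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("displacement field contains non-finite values")


# ---------------------------------------------------------------------------
# array-level helpers


def _rotate_array(arr: np.ndarray, angle_deg: float, order: int, cval: float) -> np.ndarray:
    """Rotate about the canvas centre ((H-1)/2, (W-1)/2).

    Positive angles map the content so that ``rotate(90)`` equals
    ``np.fliplr(arr).T`` on a square canvas.
    """
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # snap the quarter-turn cases to exact 0/±1 so they become pure index
    # permutations instead of picking up one-ulp interpolation at the border
    c, s = (round(v) if abs(v - round(v)) < 1e-12 else v for v in (c, s))
    # output -> input coordinate map
    matrix = np.array([[c, -s], [s, c]])
    center = (np.asarray(arr.shape, dtype=np.float64) - 1.0) / 2.0
    offset = center - matrix @ center
    return ndimage.affine_transform(
        arr, matrix, offset=offset, order=order, mode="constant", cval=cval
    )


def _elastic_array(arr: np.ndarray, field: DisplacementField, order: int) -> np.ndarray:
    """Resample ``arr`` at ``(r + dy, c + dx)`` with reflect padding."""
    h, w = arr.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")
    coords = np.stack([rr + field.dy, cc + field.dx])
    return ndimage.map_coordinates(arr, coords, order=order, mode="reflect")


def _border_median(arr: np.ndarray) -> float:
    border = np.concatenate([arr[0, :], arr[-1, :], arr[1:-1, 0], arr[1:-1, -1]])
    return float(np.median(border))


# ---------------------------------------------------------------------------
# paired transforms


def rotate_pair(
    img: Micrograph, mask: LabelMask, angle: float
) -> tuple[Micrograph, LabelMask]:
    """Rotate an image/mask pair about the canvas centre.

    The image is interpolated bilinearly with out-of-canvas regions filled
    with the border-median intensity; the mask uses nearest-neighbour
    sampling (fill 0) and is re-binarized.
    """
    if not -90.0 <= angle <= 90.0:
        raise ValueError(f"rotation angle must lie in [-90, 90] degrees, got {angle}")
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if angle == 0.0:
        return img, mask
    rot_img = _rotate_array(img.pixels, angle, order=1, cval=_border_median(img.pixels))
    rot_mask = _rotate_array(mask.pixels.astype(np.float64), angle, order=0, cval=0.0)
    return (
        Micrograph(np.clip(rot_img, 0.0, 1.0), img.pixels_per_10um),
        LabelMask((rot_mask > 0.5).astype(np.uint8)),
    )


def flip_pair(
    img: Micrograph, mask: LabelMask, axis: str
) -> tuple[Micrograph, LabelMask]:
    """Mirror both image and mask along ``"horizontal"`` (left-right,
    columns reversed) or ``"vertical"`` (top-bottom, rows reversed)."""
    if axis == "horizontal":
        ax = 1
    elif axis == "vertical":
        ax = 0
    else:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    return (
        Micrograph(np.flip(img.pixels, axis=ax).copy(), img.pixels_per_10um),
        LabelMask(np.flip(mask.pixels, axis=ax).copy()),
    )


def make_displacement(shape: tuple[int, int], p: ElasticParams) -> DisplacementField:
    """Draw and smooth a random displacement field.

    Raw displacements are i.i.d. uniform on (-1, 1) and smoothed with a
    unit-sum Gaussian of std ``sigma``.  Smoothing a bounded field with a
    unit-sum kernel shrinks its amplitude by roughly ``1/sigma`` (the more
    it is averaged, the closer to zero it gets), which would make the
    displacement scale depend on ``sigma``; each smoothed field is
    therefore rescaled to unit maximum amplitude before multiplying by
    ``alpha``, so ``alpha`` is the peak displacement in pixels and
    ``|dx|, |dy| <= alpha`` holds exactly.
    """
    rng = np.random.default_rng(p.seed)
    dx = rng.uniform(-1.0, 1.0, size=shape)
    dy = rng.uniform(-1.0, 1.0, size=shape)
    out = []
    for field in (dx, dy):
        sm = ndimage.gaussian_filter(field, p.sigma, mode="reflect", truncate=_TRUNCATE)
        peak = np.abs(sm).max()
        if peak > 0:
            sm /= peak
        out.append(p.alpha * sm)
    return DisplacementField(dx=out[0], dy=out[1])


def elastic_pair(
    img: Micrograph,
    mask: LabelMask,
    p: ElasticParams,
    field: DisplacementField | None = None,
) -> tuple[Micrograph, LabelMask]:
    """Elastically deform an image/mask pair with a shared field.

    ``field`` may be injected directly (e.g. for testing); otherwise it is
    generated from ``p``.  Image sampling is bilinear, mask sampling is
    nearest-neighbour followed by re-binarization; source coordinates
    outside the canvas are reflected.
    """
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if field is None:
        field = make_displacement(img.shape, p)
    if field.dx.shape != img.shape:
        raise ValueError("displacement field shape differs from image shape")
    if p.alpha == 0.0 and field is not None and not field.dx.any() and not field.dy.any():
        return img, mask
    out_img = _elastic_array(img.pixels, field, order=1)
    out_mask = _elastic_array(mask.pixels.astype(np.float64), field, order=0)
    return (
        Micrograph(np.clip(out_img, 0.0, 1.0), img.pixels_per_10um),
        LabelMask((out_mask > 0.5).astype(np.uint8)),
    )


# ---------------------------------------------------------------------------
# dataset expansion policy: each original spawns one rotated, one flipped and
# one elastically deformed copy, i.e. N originals -> 4N pairs.


def augment_manifest(
    manifest: DatasetManifest,
    out_dir: str | Path,
    seed: int,
    alpha_range: tuple[float, float] = (6.0, 12.0),
    sigma_range: tuple[float, float] = (8.0, 12.0),
) -> DatasetManifest:
    """Expand a dataset 4x: original + rotated + flipped + elastic copies.

    Rotation angles are drawn uniformly from [-90, 90] degrees, the flip
    axis uniformly from {horizontal, vertical}, and elastic parameters from
    the given ranges.  Images, masks and a new ``manifest.csv`` are written
    under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries: list[ManifestEntry] = []

    for i, entry in enumerate(manifest.entries):
        img = read_image(manifest.image_path(entry))
        mp = manifest.mask_path(entry)
        if mp is not None:
            mask = read_mask(mp)
        else:
            mask = LabelMask(np.zeros(img.shape, dtype=np.uint8))

        angle = float(rng.uniform(-90.0, 90.0))
        axis = "horizontal" if rng.integers(2) == 0 else "vertical"
        ep = ElasticParams(
            alpha=float(rng.uniform(*alpha_range)),
            sigma=float(rng.uniform(*sigma_range)),
            seed=int(rng.integers(2**31)),
        )
        variants = [
            ("orig", img, mask),
            ("rot", *rotate_pair(img, mask, angle)),
            ("flip", *flip_pair(img, mask, axis)),
            ("elastic", *elastic_pair(img, mask, ep)),
        ]
        for tag, v_img, v_mask in variants:
            img_name = f"img_{i:05d}_{tag}.png"
            mask_name = f"mask_{i:05d}_{tag}.png"
            write_image(v_img, out_dir / img_name)
            write_mask(v_mask, out_dir / mask_name)
            entries.append(ManifestEntry(img_name, mask_name, entry.label))

    out = DatasetManifest(entries, root=out_dir)
    save_manifest(out, out_dir / "manifest.csv")
    return out
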