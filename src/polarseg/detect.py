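"""Polar-body presence decision and localisation from a probability map.

The trained network outputs a per-pixel probability map that typically
contains several connected blobs of elevated probability.  The detector
applies a region-level non-maximum suppression with two constraints: a
candidate region is kept only if its maximum probability reaches
``prob_threshold`` (default 0.5) and its pixel count reaches ``min_area``.
Among the survivors the region with the highest maximum probability wins
(ties broken by larger area, then by topmost-leftmost centroid), and the
polar-body centre is reported as the mean of the winning region's pixel
coordinates.  If no region survives, the image is declared to contain no
polar body.

Candidate regions are formed at a lower ``support_threshold`` so that the
max-probability constraint acts on whole blobs rather than on the pixels
that already passed 0.5 — this keeps the two printed constraints
independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Micrograph

__all__ = ["NMSConfig", "Region", "DetectionResult", "find_regions", "nonmax_suppress", "region_centroid", "detect", "detect_from_map"]


@dataclass(frozen=True)
class NMSConfig:
    prob_threshold: float = 0.5
    support_threshold: float = 0.1
    min_area: int = 50
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.support_threshold <= self.prob_threshold < 1.0:
            raise ValueError(
                "need 0 < support_threshold <= prob_threshold < 1, got "
                f"{self.support_threshold}, {self.prob_threshold}"
            )
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class Region:
    """One connected candidate region of the probability map."""

    coords: np.ndarray  # (n, 2) array of (row, col) pixel coordinates
    max_prob: float

    @property
    def area(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> tuple[float, float]:
        return region_centroid(self)


@dataclass(frozen=True)
class DetectionResult:
    present: bool
    centroid: tuple[float, float] | None
    confidence: float
    area: int

    def __post_init__(self) -> None:
        if self.present != (self.centroid is not None):
            raise ValueError("centroid must be given exactly when present")


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def find_regions(pmap: np.ndarray, cfg: NMSConfig = NMSConfig()) -> list[Region]:
    """Connected components of ``pmap >= support_threshold``."""
    pmap = np.asarray(pmap, dtype=np.float64)
    labeled, n = ndimage.label(pmap >= cfg.support_threshold, structure=_STRUCTURES[cfg.connectivity])
    regions = []
    for i in range(1, n + 1):
        coords = np.argwhere(labeled == i)
        regions.append(Region(coords=coords, max_prob=float(pmap[tuple(coords.T)].max())))
    return regions


def region_centroid(region: Region) -> tuple[float, float]:
    """Mean (row, col) of all pixel locations in the region."""
    if len(region.coords) == 0:
        raise ValueError("cannot take the centroid of an empty region")
    r, c = region.coords.mean(axis=0)
    return float(r), float(c)


def nonmax_suppress(regions: list[Region], cfg: NMSConfig = NMSConfig()) -> Region | None:
    """Keep regions meeting both constraints and return the best, if any.

    Survivors need ``max_prob >= prob_threshold`` and ``area >= min_area``.
    The winner has the highest max probability; ties fall to the larger
    area, then to the topmost-leftmost centroid.
    """
    survivors = [r for r in regions if r.max_prob >= cfg.prob_threshold and r.area >= cfg.min_area]
    if not survivors:
        return None
    return min(survivors, key=lambda r: (-r.max_prob, -r.area, r.centroid))


def detect_from_map(pmap: np.ndarray, cfg: NMSConfig = NMSConfig()) -> DetectionResult:
    """Presence decision + centroid from an already-computed probability map."""
    winner = nonmax_suppress(find_regions(pmap, cfg), cfg)
    if winner is None:
        return DetectionResult(present=False, centroid=None, confidence=0.0, area=0)
    return DetectionResult(
        present=True,
        centroid=region_centroid(winner),
        confidence=winner.max_prob,
        area=winner.area,
    )


def detect(net, img: Micrograph, cfg: NMSConfig = NMSConfig()) -> DetectionResult:
    """Segment an image with ``net`` and localise the polar body.

    ``net`` is anything with a ``predict(Micrograph) -> ndarray`` method
    returning a probability map of the image's shape.
    """
    pmap = net.predict(img)
    if pmap.shape != img.shape:
        raise ValueError(f"network returned map of shape {pmap.shape} for image {img.shape}")
    return detect_from_map(pmap, cfg)
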