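"""Synthetic oocyte-micrograph generator with paired ground-truth masks.

A rendered scene emulates a brightfield micrograph of an oocyte held
between micropipettes: a roughly circular cell with a textured cytoplasm,
a brighter zona pellucida ring, and (for positive samples) a small dark
elliptical polar body with a bright rim sitting in the perivitelline gap
between cytoplasm and zona.  Three difficulty axes mirror what happens
during cell rotation:

* ``defocused`` — the polar body drifts off the focal plane; modelled by
  convolving its contribution to the image with a Gaussian point-spread
  function (the annotation mask is unaffected: the structure is still
  there, just blurred);
* ``deformed`` — micropipette contact squeezes the cell; modelled by an
  elastic deformation applied jointly to image and mask;
* ``mixed`` — defocus and deformation are switched on independently.

Photorealism is explicitly not the goal: downstream acceptance rests on
the geometry of the mask and the detectability of the polar body, and the
cytoplasm texture is made busy enough that plain intensity thresholding
does not solve the task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .augment import ElasticParams, _elastic_array, make_displacement
from .io import (
    DatasetManifest,
    LabelMask,
    ManifestEntry,
    Micrograph,
    save_manifest,
    write_image,
    write_mask,
)

__all__ = ["SceneParams", "render_scene", "sample_params", "generate_dataset", "DIFFICULTIES"]

DIFFICULTIES = ("clear", "defocused", "deformed", "mixed")

DEFAULT_SIZE = (256, 256)


@dataclass(frozen=True)
class SceneParams:
    """Full description of one synthetic oocyte scene.

    The polar body centre sits on the circle of radius
    ``cell_radius - zona_thickness / 2`` around ``cell_center`` (the
    perivitelline gap between cytoplasm and zona pellucida), at polar angle
    ``pb_center_angle``.
    """

    cell_center: tuple[float, float]
    cell_radius: float
    zona_thickness: float
    polar_body_present: bool
    pb_center_angle: float
    pb_semi_axes: tuple[float, float]
    pb_orientation: float
    pb_defocus_sigma: float = 0.0
    deformation: ElasticParams | None = None
    pipette_present: bool = True
    brightness: float = 0.85
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        a, b = self.pb_semi_axes
        if self.polar_body_present:
            if min(a, b) < 2.0:
                raise ValueError(f"pb semi-axes must each be >= 2 px, got {self.pb_semi_axes}")
            if max(a, b) > self.cell_radius / 3.0:
                raise ValueError(
                    f"pb semi-axes must be <= cell_radius/3 = {self.cell_radius / 3:.1f}, "
                    f"got {self.pb_semi_axes}"
                )
        if not 0.3 <= self.brightness <= 1.0:
            raise ValueError(f"brightness must lie in [0.3, 1.0], got {self.brightness}")
        if self.pb_defocus_sigma < 0:
            raise ValueError("pb_defocus_sigma must be >= 0")
        if self.cell_radius <= self.zona_thickness:
            raise ValueError("cell_radius must exceed zona_thickness")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def pb_center(self) -> tuple[float, float]:
        rho = self.cell_radius - self.zona_thickness / 2.0
        r0, c0 = self.cell_center
        return (
            r0 + rho * math.sin(self.pb_center_angle),
            c0 + rho * math.cos(self.pb_center_angle),
        )


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean low-frequency Gaussian random field, roughly unit amplitude."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma, mode="reflect")
    scale = sm.std()
    return sm / scale if scale > 0 else sm


def _soft_edge(signed: np.ndarray, width: float = 1.0) -> np.ndarray:
    """Anti-aliased inside-ness: 1 well inside (signed >= width), 0 outside."""
    return np.clip(signed / width / 2.0 + 0.5, 0.0, 1.0)


def render_scene(p: SceneParams, size: tuple[int, int] = DEFAULT_SIZE) -> tuple[Micrograph, LabelMask]:
    """Render one scene and its ground-truth polar-body mask.

    Deterministic for a fixed ``p`` (texture and noise derive from
    ``p.seed``).  Defocus blurs only the polar body's contribution to the
    image and never touches the mask; elastic deformation, when present,
    is applied jointly to image and mask.
    """
    p.validate()
    h, w = size
    if h % 16 or w % 16:
        raise ValueError(f"canvas size must be divisible by 16, got {size}")
    rng = np.random.default_rng(p.seed)
    b = p.brightness
    rr, cc = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")
    r0, c0 = p.cell_center
    dist = np.hypot(rr - r0, cc - c0)

    # background with gentle illumination gradient
    grad = _smooth_noise(rng, (h, w), sigma=max(h, w) / 4)
    scene = b * (0.90 + 0.03 * grad)

    # cytoplasm: darker disc with low-frequency multiplicative texture
    inner_r = p.cell_radius - p.zona_thickness
    cyto = _soft_edge(inner_r - dist)
    texture = 1.0 + 0.16 * _smooth_noise(rng, (h, w), sigma=6.0)
    scene = scene * (1 - cyto) + cyto * b * 0.55 * texture

    # zona pellucida: brighter annulus with thin dark boundary lines
    zona = _soft_edge(dist - inner_r) * _soft_edge(p.cell_radius - dist)
    scene = scene * (1 - zona) + zona * b * 0.76
    for edge_r in (inner_r, p.cell_radius):
        line = _soft_edge(1.2 - np.abs(dist - edge_r))
        scene = scene * (1 - 0.35 * line)

    # micropipettes: holding pipette (two bars) from the left, injection
    # pipette (one bar) from the right, both touching the cell edge
    if p.pipette_present:
        bar_t = max(2.0, 0.012 * w)
        left_reach = cc <= c0 - p.cell_radius + 2.0
        gap = 0.14 * h
        for row_off in (-gap, gap):
            bar = (np.abs(rr - (r0 + row_off)) <= bar_t) & left_reach
            scene[bar] *= 0.5
        right_reach = cc >= c0 + p.cell_radius - 2.0
        bar = (np.abs(rr - r0) <= bar_t * 1.4) & right_reach
        scene[bar] *= 0.45

    mask = np.zeros((h, w), dtype=np.uint8)
    if p.polar_body_present:
        # elliptical polar body: dark interior, bright rim just outside
        pr, pc = p.pb_center
        a, bb = p.pb_semi_axes
        co, so = math.cos(p.pb_orientation), math.sin(p.pb_orientation)
        u = (rr - pr) * co + (cc - pc) * so
        v = -(rr - pr) * so + (cc - pc) * co
        # signed "radius" distance approximation for anti-aliasing
        e = np.sqrt((u / a) ** 2 + (v / bb) ** 2)
        r_eff = min(a, bb)
        inside = _soft_edge((1.0 - e) * r_eff)
        rim = _soft_edge((1.25 - e) * r_eff) - inside
        pb_tex = 1.0 + 0.10 * _smooth_noise(rng, (h, w), sigma=2.5)
        with_pb = scene * (1 - inside) + inside * b * 0.36 * pb_tex
        with_pb = with_pb * (1 - rim) + rim * b * 0.88
        delta = with_pb - scene
        if p.pb_defocus_sigma > 0:
            delta = ndimage.gaussian_filter(delta, p.pb_defocus_sigma, mode="reflect")
        scene = scene + delta
        mask = (e <= 1.0).astype(np.uint8)

    if p.deformation is not None and p.deformation.alpha > 0:
        field = make_displacement((h, w), p.deformation)
        scene = _elastic_array(scene, field, order=1)
        mask = (_elastic_array(mask.astype(np.float64), field, order=0) > 0.5).astype(np.uint8)

    if p.noise_sigma > 0:
        scene = scene + rng.normal(0.0, p.noise_sigma, size=(h, w))

    return Micrograph(np.clip(scene, 0.0, 1.0)), LabelMask(mask)


def sample_params(
    difficulty: str,
    rng_seed: int,
    size: tuple[int, int] = DEFAULT_SIZE,
) -> SceneParams:
    """Draw scene parameters for one positive sample at a given difficulty.

    ``clear`` renders an in-focus undeformed polar body; ``defocused``
    draws a PSF std from [2, 6] px; ``deformed`` draws an elastic
    displacement scale from [4, 10] px; ``mixed`` switches each effect on
    independently.  Polar-body semi-axes are drawn from [4, 16] px in all
    modes (clipped to the cell_radius/3 geometric bound).
    """
    if difficulty not in DIFFICULTIES:
        raise ValueError(f"unknown difficulty {difficulty!r}; expected one of {DIFFICULTIES}")
    rng = np.random.default_rng(rng_seed)
    h, w = size
    scale = min(h, w) / 256.0

    cell_radius = float(rng.uniform(0.68, 0.82) * min(h, w) / 2.0)
    cell_center = (
        h / 2.0 + float(rng.uniform(-6.0, 6.0)) * scale,
        w / 2.0 + float(rng.uniform(-6.0, 6.0)) * scale,
    )
    zona_thickness = float(rng.uniform(10.0, 14.0)) * scale

    a = float(rng.uniform(4.0, 16.0))
    b = float(rng.uniform(4.0, 16.0))
    bound = cell_radius / 3.0
    a, b = min(a, bound), min(b, bound)

    defocus = 0.0
    deformation: ElasticParams | None = None
    if difficulty == "defocused":
        defocus = float(rng.uniform(2.0, 6.0))
    elif difficulty == "deformed":
        deformation = ElasticParams(
            alpha=float(rng.uniform(4.0, 10.0)),
            sigma=float(rng.uniform(8.0, 12.0)),
            seed=int(rng.integers(2**31)),
        )
    elif difficulty == "mixed":
        if rng.uniform() < 0.5:
            defocus = float(rng.uniform(2.0, 6.0))
        if rng.uniform() < 0.5:
            deformation = ElasticParams(
                alpha=float(rng.uniform(4.0, 10.0)),
                sigma=float(rng.uniform(8.0, 12.0)),
                seed=int(rng.integers(2**31)),
            )

    return SceneParams(
        cell_center=cell_center,
        cell_radius=cell_radius,
        zona_thickness=zona_thickness,
        polar_body_present=True,
        pb_center_angle=float(rng.uniform(0.0, 2.0 * math.pi)),
        pb_semi_axes=(a, b),
        pb_orientation=float(rng.uniform(0.0, math.pi)),
        pb_defocus_sigma=defocus,
        deformation=deformation,
        pipette_present=bool(rng.uniform() < 0.9),
        brightness=float(rng.uniform(0.6, 1.0)),
        noise_sigma=float(rng.uniform(0.01, 0.03)),
        seed=int(rng.integers(2**31)),
    )


def generate_dataset(
    n_positive: int,
    n_negative: int,
    difficulty: str,
    out_dir: str | Path,
    seed: int,
    size: tuple[int, int] = DEFAULT_SIZE,
) -> DatasetManifest:
    """Render a dataset of positive and negative scenes plus a CSV manifest.

    Negative samples reuse the positive parameter distribution with the
    polar body switched off, so positives and negatives differ only in the
    structure of interest.  Deterministic (byte-identical files) for a
    fixed seed.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("sample counts must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries: list[ManifestEntry] = []

    labels = ["positive"] * n_positive + ["negative"] * n_negative
    for i, label in enumerate(labels):
        params = sample_params(difficulty, int(rng.integers(2**31)), size=size)
        if label == "negative":
            params = replace(params, polar_body_present=False)
        img, mask = render_scene(params, size=size)
        img_name = f"img_{i:05d}.png"
        mask_name = f"mask_{i:05d}.png"
        write_image(img, out_dir / img_name)
        write_mask(mask, out_dir / mask_name)
        entries.append(ManifestEntry(img_name, mask_name, label))

    manifest = DatasetManifest(entries, root=out_dir)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
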