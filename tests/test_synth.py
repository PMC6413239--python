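import hashlib
import math

import numpy as np
import pytest

from polarseg.augment import ElasticParams
from polarseg.synth import SceneParams, generate_dataset, render_scene, sample_params


def _clean_params(**overrides):
    """A well-separated polar body on a 256x256 canvas, no pipettes/noise."""
    base = dict(
        cell_center=(128.0, 128.0),
        cell_radius=94.0,
        zona_thickness=12.0,
        polar_body_present=True,
        pb_center_angle=math.pi,  # left of centre: (128, 128 - 88) = (128, 40)
        pb_semi_axes=(8.0, 8.0),
        pb_orientation=0.0,
        pb_defocus_sigma=0.0,
        deformation=None,
        pipette_present=False,
        brightness=0.85,
        noise_sigma=0.0,
        seed=42,
    )
    base.update(overrides)
    return SceneParams(**base)


class TestRenderScene:
    def test_negative_scene_has_empty_mask(self):
        img, mask = render_scene(_clean_params(polar_body_present=False))
        assert mask.is_empty()
        assert 0.0 <= img.pixels.min() and img.pixels.max() <= 1.0

    def test_mask_centroid_matches_analytic_ellipse_centre(self):
        # circular pb of radius 8 centred at (128, 40)
        _, mask = render_scene(_clean_params())
        got = mask.foreground_centroid()
        assert got is not None
        assert np.hypot(got[0] - 128.0, got[1] - 40.0) <= 1.0

    def test_mask_equals_analytic_ellipse_rasterization(self):
        p = _clean_params(pb_semi_axes=(10.0, 6.0), pb_orientation=0.7)
        _, mask = render_scene(p)
        rr, cc = np.mgrid[:256, :256].astype(float)
        pr, pc = p.pb_center
        co, so = math.cos(p.pb_orientation), math.sin(p.pb_orientation)
        u = (rr - pr) * co + (cc - pc) * so
        v = -(rr - pr) * so + (cc - pc) * co
        oracle = ((u / 10.0) ** 2 + (v / 6.0) ** 2 <= 1.0).astype(np.uint8)
        assert np.array_equal(mask.pixels, oracle)

    def test_defocus_changes_image_only_near_polar_body(self):
        sharp_img, sharp_mask = render_scene(_clean_params())
        blur_img, blur_mask = render_scene(_clean_params(pb_defocus_sigma=5.0))
        assert np.array_equal(sharp_mask.pixels, blur_mask.pixels)
        diff = np.abs(blur_img.pixels - sharp_img.pixels)
        assert diff.max() > 0  # the defocus did something
        # outside the pb neighbourhood (ellipse + rim extent plus the 4-sigma
        # truncated PSF support, which is a square) the scene is untouched
        rr, cc = np.mgrid[:256, :256].astype(float)
        cheb = np.maximum(np.abs(rr - 128.0), np.abs(cc - 40.0))
        far = cheb > 8.0 * 1.5 + 4 * 5.0 + 2
        assert np.allclose(diff[far], 0.0, atol=1e-12)

    def test_deterministic_for_fixed_seed(self):
        a_img, a_mask = render_scene(_clean_params(noise_sigma=0.02))
        b_img, b_mask = render_scene(_clean_params(noise_sigma=0.02))
        assert np.array_equal(a_img.pixels, b_img.pixels)
        assert np.array_equal(a_mask.pixels, b_mask.pixels)

    def test_deformation_moves_mask_and_image_jointly(self):
        p = _clean_params(deformation=ElasticParams(alpha=8.0, sigma=10.0, seed=3))
        img, mask = render_scene(p)
        _, base_mask = render_scene(_clean_params())
        assert not mask.is_empty()
        assert not np.array_equal(mask.pixels, base_mask.pixels)

    @pytest.mark.parametrize(
        "overrides",
        [
            {"pb_semi_axes": (1.0, 8.0)},       # below 2 px minimum
            {"pb_semi_axes": (40.0, 8.0)},      # above cell_radius / 3
            {"brightness": 0.1},
            {"pb_defocus_sigma": -1.0},
        ],
    )
    def test_invalid_params_rejected(self, overrides):
        with pytest.raises(ValueError):
            render_scene(_clean_params(**overrides))

    def test_size_must_be_divisible_by_16(self):
        with pytest.raises(ValueError):
            render_scene(_clean_params(), size=(250, 256))


class TestSampleParams:
    def test_deterministic(self):
        a = sample_params("clear", 1)
        b = sample_params("clear", 1)
        assert a == b

    def test_clear_has_no_defocus_or_deformation(self):
        for seed in range(10):
            p = sample_params("clear", seed)
            assert p.pb_defocus_sigma == 0.0 and p.deformation is None

    def test_defocused_sigma_in_range(self):
        for seed in range(20):
            p = sample_params("defocused", seed)
            assert 2.0 <= p.pb_defocus_sigma <= 6.0

    def test_deformed_alpha_in_range(self):
        for seed in range(20):
            p = sample_params("deformed", seed)
            assert p.deformation is not None and 4.0 <= p.deformation.alpha <= 10.0

    def test_mixed_spans_stated_size_range(self):
        sizes = []
        for seed in range(1000):
            p = sample_params("mixed", seed)
            sizes.extend(p.pb_semi_axes)
        assert min(sizes) <= 5.0 and max(sizes) >= 15.0

    def test_params_satisfy_scene_invariants(self):
        for difficulty in ("clear", "defocused", "deformed", "mixed"):
            for seed in range(5):
                sample_params(difficulty, seed).validate()

    def test_unknown_difficulty(self):
        with pytest.raises(ValueError):
            sample_params("nightmare", 0)


class TestGenerateDataset:
    def test_counts_and_labels(self, tmp_path):
        m = generate_dataset(6, 4, "clear", tmp_path / "d", seed=2, size=(64, 64))
        assert len(m) == 10
        assert sum(e.label == "positive" for e in m.entries) == 6
        assert sum(e.label == "negative" for e in m.entries) == 4

    def test_positive_masks_nonempty_negative_masks_empty(self, tmp_path):
        from polarseg.io import read_mask

        m = generate_dataset(4, 3, "clear", tmp_path / "d", seed=8, size=(64, 64))
        for e in m.entries:
            mask = read_mask(m.mask_path(e))
            assert mask.is_empty() == (e.label == "negative")

    def test_only_negatives(self, tmp_path):
        from polarseg.io import read_mask

        m = generate_dataset(0, 5, "mixed", tmp_path / "d", seed=0, size=(64, 64))
        assert len(m) == 5
        assert all(read_mask(m.mask_path(e)).is_empty() for e in m.entries)

    def test_reproducible_bytes(self, tmp_path):
        def digest(root):
            h = hashlib.sha256()
            for f in sorted(root.rglob("*")):
                if f.is_file():
                    h.update(f.name.encode() + f.read_bytes())
            return h.hexdigest()

        generate_dataset(3, 2, "mixed", tmp_path / "a", seed=7, size=(64, 64))
        generate_dataset(3, 2, "mixed", tmp_path / "b", seed=7, size=(64, 64))
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_negative_counts_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(-1, 0, "clear", tmp_path / "d", seed=0)
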