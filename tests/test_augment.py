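import numpy as np
import pytest

from polarseg.augment import (
    DisplacementField,
    ElasticParams,
    augment_manifest,
    elastic_pair,
    flip_pair,
    make_displacement,
    rotate_pair,
)
from polarseg.io import LabelMask, Micrograph


def _single_pixel_mask(shape, r, c):
    m = np.zeros(shape, dtype=np.uint8)
    m[r, c] = 1
    return LabelMask(m)


class TestRotate:
    def test_zero_angle_is_identity(self, checker_image, dot_mask):
        img, mask = rotate_pair(checker_image, dot_mask, 0.0)
        assert np.array_equal(img.pixels, checker_image.pixels)
        assert np.array_equal(mask.pixels, dot_mask.pixels)

    def test_quarter_turn_matches_index_permutation(self, checker_image, dot_mask):
        # On a square canvas this 90-degree rotation about the centre is the
        # exact permutation B[r, c] = A[H-1-c, r], i.e. np.flipud(A).T.
        img, mask = rotate_pair(checker_image, dot_mask, 90.0)
        assert np.allclose(img.pixels, np.flipud(checker_image.pixels).T, atol=1e-9)
        assert np.array_equal(mask.pixels, np.flipud(dot_mask.pixels).T)

    @pytest.mark.parametrize("angle", [-90, -37.5, 12.0, 66.6])
    def test_mask_stays_binary(self, checker_image, dot_mask, angle):
        _, mask = rotate_pair(checker_image, dot_mask, angle)
        assert set(np.unique(mask.pixels)) <= {0, 1}

    @pytest.mark.parametrize("angle", [-90.1, 91.0, 180.0])
    def test_angle_out_of_range(self, checker_image, dot_mask, angle):
        with pytest.raises(ValueError):
            rotate_pair(checker_image, dot_mask, angle)

    @pytest.mark.parametrize("angle", [-60.0, 33.0, 90.0])
    def test_centroid_moves_rigidly(self, checker_image, angle):
        mask = _single_pixel_mask((64, 64), 20, 45)
        _, rot = rotate_pair(checker_image, mask, angle)
        theta = np.deg2rad(angle)
        ctr = 31.5
        # forward map of the content: the source pixel lands at R(-theta)
        dr, dc = 20 - ctr, 45 - ctr
        exp_r = ctr + np.cos(theta) * dr + np.sin(theta) * dc
        exp_c = ctr - np.sin(theta) * dr + np.cos(theta) * dc
        got = rot.foreground_centroid()
        assert got is not None
        assert np.hypot(got[0] - exp_r, got[1] - exp_c) <= 1.0


class TestFlip:
    def test_double_flip_is_identity(self, checker_image, dot_mask):
        for axis in ("horizontal", "vertical"):
            i1, m1 = flip_pair(checker_image, dot_mask, axis)
            i2, m2 = flip_pair(i1, m1, axis)
            assert np.array_equal(i2.pixels, checker_image.pixels)
            assert np.array_equal(m2.pixels, dot_mask.pixels)

    def test_horizontal_flip_index_arithmetic(self):
        img = Micrograph(np.zeros((256, 256)))
        mask = _single_pixel_mask((256, 256), 10, 20)
        _, flipped = flip_pair(img, mask, "horizontal")
        assert flipped.pixels[10, 235] == 1
        assert flipped.pixels.sum() == 1

    def test_flip_preserves_foreground_count(self, checker_image, dot_mask):
        for axis in ("horizontal", "vertical"):
            _, m = flip_pair(checker_image, dot_mask, axis)
            assert m.pixels.sum() == dot_mask.pixels.sum()

    def test_unknown_axis(self, checker_image, dot_mask):
        with pytest.raises(ValueError):
            flip_pair(checker_image, dot_mask, "diagonal")


class TestDisplacement:
    def test_zero_alpha_gives_zero_field(self):
        f = make_displacement((32, 32), ElasticParams(alpha=0.0, sigma=4.0, seed=3))
        assert not f.dx.any() and not f.dy.any()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_field_bounded_by_alpha(self, seed):
        # unit-sum Gaussian smoothing of values in (-1, 1), scaled by alpha
        p = ElasticParams(alpha=7.0, sigma=3.0, seed=seed)
        f = make_displacement((48, 48), p)
        assert np.abs(f.dx).max() <= p.alpha
        assert np.abs(f.dy).max() <= p.alpha

    def test_deterministic_under_seed(self):
        p = ElasticParams(alpha=5.0, sigma=4.0, seed=11)
        f1 = make_displacement((32, 32), p)
        f2 = make_displacement((32, 32), p)
        assert np.array_equal(f1.dx, f2.dx) and np.array_equal(f1.dy, f2.dy)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ElasticParams(alpha=-1.0, sigma=4.0)
        with pytest.raises(ValueError):
            ElasticParams(alpha=1.0, sigma=0.0)


class TestElastic:
    def test_zero_alpha_is_identity(self, checker_image, dot_mask):
        img, mask = elastic_pair(checker_image, dot_mask, ElasticParams(0.0, 8.0, 1))
        assert np.array_equal(img.pixels, checker_image.pixels)
        assert np.array_equal(mask.pixels, dot_mask.pixels)

    def test_constant_field_shifts_sampling(self):
        # out[r, c] = in[r + dy, c + dx]: with dx=3 the foreground pixel at
        # column 40 appears at column 37.
        img = Micrograph(np.zeros((64, 64)))
        mask = _single_pixel_mask((64, 64), 30, 40)
        field = DisplacementField(dx=np.full((64, 64), 3.0), dy=np.zeros((64, 64)))
        _, out = elastic_pair(img, mask, ElasticParams(3.0, 8.0, 0), field=field)
        assert out.pixels[30, 37] == 1
        assert out.pixels.sum() == 1

    def test_smooth_field_approximately_preserves_area(self):
        # disk of radius 16 on a 64x64 canvas; alpha = 6 peak displacement,
        # sigma = 8 smoothing.  A smooth warp is locally near-affine, so the
        # area is preserved in expectation; individual seeds can stretch or
        # squeeze the disk by up to ~|d|/r = 6/16 per axis, hence the wider
        # per-seed envelope (calibrated by this same 100-seed Monte Carlo).
        rr, cc = np.mgrid[:64, :64]
        disk = ((rr - 32) ** 2 + (cc - 32) ** 2 <= 16**2).astype(np.uint8)
        img = Micrograph(np.zeros((64, 64)))
        mask = LabelMask(disk)
        area0 = disk.sum()
        ratios = []
        for seed in range(100):
            p = ElasticParams(alpha=6.0, sigma=8.0, seed=seed)
            _, out = elastic_pair(img, mask, p)
            ratios.append(out.pixels.sum() / area0)
            assert 0.6 * area0 <= out.pixels.sum() <= 1.4 * area0
            assert out.pixels.sum() > 0  # stays connected to a nonempty region
        assert abs(np.mean(ratios) - 1.0) <= 0.05

    def test_same_seed_reproducible(self, checker_image, dot_mask):
        p = ElasticParams(alpha=9.0, sigma=9.0, seed=21)
        a = elastic_pair(checker_image, dot_mask, p)
        b = elastic_pair(checker_image, dot_mask, p)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)


class TestAugmentManifest:
    def test_one_to_four_policy(self, tiny_dataset, tmp_path):
        out = augment_manifest(tiny_dataset, tmp_path / "aug", seed=9)
        assert len(out) == 4 * len(tiny_dataset)
        # labels carried over in order, each original spawning 4 entries
        for i, entry in enumerate(tiny_dataset.entries):
            for j in range(4):
                assert out.entries[4 * i + j].label == entry.label

    def test_outputs_stay_binary_and_paired(self, tiny_dataset, tmp_path):
        from polarseg.io import read_image, read_mask

        out = augment_manifest(tiny_dataset, tmp_path / "aug", seed=9)
        for entry in out.entries[:8]:
            img = read_image(out.image_path(entry))
            mask = read_mask(out.mask_path(entry))
            assert img.shape == mask.shape
            assert set(np.unique(mask.pixels)) <= {0, 1}
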