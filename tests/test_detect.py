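import numpy as np
import pytest

from polarseg.detect import (
    DetectionResult,
    NMSConfig,
    Region,
    detect,
    detect_from_map,
    find_regions,
    nonmax_suppress,
    region_centroid,
)
from polarseg.io import Micrograph

from _oracles import brute_force_detect

CFG = NMSConfig(prob_threshold=0.5, support_threshold=0.1, min_area=50, connectivity=8)
SMALL = NMSConfig(prob_threshold=0.5, support_threshold=0.1, min_area=5, connectivity=8)


class _StubNet:
    """Stand-in segmenter returning a fixed probability map."""

    def __init__(self, pmap):
        self._pmap = np.asarray(pmap, dtype=float)

    def predict(self, img):
        return self._pmap


def _disk_map(shape, center, radius, value):
    rr, cc = np.mgrid[: shape[0], : shape[1]].astype(float)
    pmap = np.zeros(shape)
    pmap[np.hypot(rr - center[0], cc - center[1]) <= radius] = value
    return pmap


class TestFindRegions:
    def test_all_zero_map_gives_no_regions(self):
        assert find_regions(np.zeros((32, 32)), CFG) == []

    def test_two_disjoint_blocks(self):
        pmap = np.zeros((32, 32))
        pmap[2:7, 2:7] = 0.9
        pmap[20:25, 10:15] = 0.9
        regions = find_regions(pmap, CFG)
        assert len(regions) == 2
        assert all(r.area == 25 and r.max_prob == pytest.approx(0.9) for r in regions)

    def test_below_support_threshold_ignored(self):
        pmap = np.zeros((32, 32))
        pmap[5:10, 5:10] = 0.05
        assert find_regions(pmap, CFG) == []

    def test_diagonal_connectivity_distinction(self):
        pmap = np.zeros((8, 8))
        pmap[0, 0] = pmap[1, 1] = 0.9  # touching only diagonally
        assert len(find_regions(pmap, NMSConfig(connectivity=8, min_area=1))) == 1
        assert len(find_regions(pmap, NMSConfig(connectivity=4, min_area=1))) == 2


class TestNonmaxSuppress:
    def test_low_max_region_suppressed(self):
        pmap = np.zeros((32, 32))
        pmap[2:12, 2:12] = 0.7
        pmap[20:30, 20:30] = 0.45
        winner = nonmax_suppress(find_regions(pmap, CFG), CFG)
        assert winner is not None and winner.max_prob == pytest.approx(0.7)

    def test_min_area_constraint(self):
        pmap = np.zeros((32, 32))
        pmap[2:9, 2:9] = 0.8  # 49 px < min_area 50
        assert nonmax_suppress(find_regions(pmap, CFG), CFG) is None

    def test_empty_region_list(self):
        assert nonmax_suppress([], CFG) is None

    def test_tie_broken_by_larger_area(self):
        pmap = np.zeros((32, 32))
        pmap[2:5, 2:5] = 0.9      # area 9
        pmap[20:25, 20:25] = 0.9  # area 25
        winner = nonmax_suppress(find_regions(pmap, SMALL), SMALL)
        assert winner.area == 25

    def test_full_tie_broken_topmost_leftmost(self):
        pmap = np.zeros((32, 32))
        pmap[2:5, 20:23] = 0.9
        pmap[20:23, 2:5] = 0.9
        winner = nonmax_suppress(find_regions(pmap, SMALL), SMALL)
        assert region_centroid(winner) == (3.0, 21.0)


class TestCentroid:
    def test_single_pixel(self):
        r = Region(coords=np.array([[10, 20]]), max_prob=0.9)
        assert region_centroid(r) == (10.0, 20.0)

    def test_two_by_two_block(self):
        coords = np.array([[10, 20], [10, 21], [11, 20], [11, 21]])
        assert region_centroid(Region(coords, 0.9)) == (10.5, 20.5)

    def test_matches_enumeration_on_arbitrary_region(self, rng):
        pts = rng.integers(0, 30, size=(37, 2))
        r = Region(coords=pts, max_prob=1.0)
        exp = (sum(p[0] for p in pts) / 37, sum(p[1] for p in pts) / 37)
        got = region_centroid(r)
        assert got[0] == pytest.approx(exp[0]) and got[1] == pytest.approx(exp[1])

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            region_centroid(Region(coords=np.empty((0, 2), dtype=int), max_prob=0.9))


class TestDetect:
    def test_zero_map_means_absent(self):
        net = _StubNet(np.zeros((128, 128)))
        img = Micrograph(np.zeros((128, 128)))
        res = detect(net, img, CFG)
        assert res == DetectionResult(present=False, centroid=None, confidence=0.0, area=0)

    def test_disk_centroid_recovered(self):
        pmap = _disk_map((128, 128), (100, 60), 8, 0.9)
        assert pmap.sum() / 0.9 >= 150
        net = _StubNet(pmap)
        res = detect(net, Micrograph(np.zeros((128, 128))), CFG)
        assert res.present
        assert np.hypot(res.centroid[0] - 100, res.centroid[1] - 60) <= 0.5

    def test_two_blobs_higher_probability_wins(self):
        pmap = _disk_map((128, 128), (100, 60), 6, 0.9)
        pmap += _disk_map((128, 128), (30, 30), 6, 0.55)
        res = detect_from_map(pmap, SMALL)
        assert np.hypot(res.centroid[0] - 100, res.centroid[1] - 60) <= 0.5

    def test_repeated_calls_identical(self, rng):
        pmap = rng.random((64, 64))
        assert detect_from_map(pmap, CFG) == detect_from_map(pmap, CFG)

    def test_raising_threshold_never_creates_detection(self, rng):
        for _ in range(30):
            pmap = rng.random((24, 24))
            lo = detect_from_map(pmap, NMSConfig(prob_threshold=0.5, min_area=5))
            hi = detect_from_map(pmap, NMSConfig(prob_threshold=0.8, min_area=5))
            if not lo.present:
                assert not hi.present

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NMSConfig(prob_threshold=0.5, support_threshold=0.6)
        with pytest.raises(ValueError):
            NMSConfig(min_area=0)
        with pytest.raises(ValueError):
            NMSConfig(connectivity=6)


class TestBruteForceEquivalence:
    """detect_from_map agrees with an exhaustive flood-fill oracle."""

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_random_small_maps(self, connectivity):
        rng = np.random.default_rng(99)
        cfg = NMSConfig(
            prob_threshold=0.5, support_threshold=0.1, min_area=4, connectivity=connectivity
        )
        for _ in range(50):
            h, w = rng.integers(4, 20, size=2)
            # quantized values make ties common, exercising the tie-breaks
            pmap = np.round(rng.random((h, w)), 1)
            got = detect_from_map(pmap, cfg)
            exp = brute_force_detect(pmap, 0.5, 0.1, 4, connectivity)
            if exp is None:
                assert not got.present
            else:
                assert got.present
                assert got.area == exp["area"]
                assert got.confidence == pytest.approx(exp["max"])
                assert got.centroid[0] == pytest.approx(exp["centroid"][0])
                assert got.centroid[1] == pytest.approx(exp["centroid"][1])
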