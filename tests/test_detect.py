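"""Foreground extraction: exact clustering, thresholding, mask combination."""

import itertools
import warnings

import numpy as np
import pytest

from wqiseg.detect import (
    DetectParams,
    boundary_by_mmd,
    combine_and_extract,
    foreground_by_kmeans,
    kmeans_1d,
)


def sse_of_labels(values, labels, k):
    sse = 0.0
    for m in range(k):
        sel = values[labels == m]
        if sel.size:
            sse += ((sel - sel.mean()) ** 2).sum()
    return sse


def exhaustive_best_sse(values, k):
    """Enumerate every contiguous split of the sorted values (the optimal
    1-D clustering is contiguous) and return the minimal SSE."""
    v = np.sort(values)
    n = v.size
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        sse = 0.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg = v[lo:hi]
            sse += ((seg - seg.mean()) ** 2).sum()
        best = min(best, sse)
    return best


class TestKmeans1d:
    @pytest.mark.parametrize("seed", range(10))
    def test_sse_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 22))  # enumeration is O(n^2), keep it tiny
        values = rng.uniform(0, 100, n)
        centers, labels = kmeans_1d(values, 3)
        assert sse_of_labels(values, labels, 3) == pytest.approx(
            exhaustive_best_sse(values, 3), abs=1e-8
        )

    def test_larger_instances_beat_or_match_lloyd(self, rng):
        # on 200-point instances the DP optimum can only be <= any Lloyd run
        from scipy.cluster.vq import kmeans2

        values = rng.uniform(0, 1, 200)
        _, labels = kmeans_1d(values, 3)
        dp_sse = sse_of_labels(values, labels, 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, lloyd_labels = kmeans2(values[:, None], 3, seed=0, minit="++")
        assert dp_sse <= sse_of_labels(values, lloyd_labels, 3) + 1e-9

    def test_centers_sorted_and_labels_consistent(self, rng):
        values = rng.normal(size=50)
        centers, labels = kmeans_1d(values, 3)
        assert np.all(np.diff(centers) > 0)
        for m in range(3):
            sel = values[labels == m]
            assert np.allclose(sel.mean(), centers[m])

    def test_degrades_when_fewer_distinct_values(self):
        with pytest.warns(UserWarning, match="degrading"):
            centers, labels = kmeans_1d(np.array([5.0, 5.0, 9.0]), 3)
        assert centers.size == 2


class TestForegroundByKmeans:
    def test_trimodal_image_selects_brightest_mode(self):
        img = np.choose(
            np.arange(90).reshape(9, 10) % 3, [10.0, 100.0, 200.0]
        )
        mask = foreground_by_kmeans(img)
        assert np.array_equal(mask, img == 200.0)

    def test_constant_image_degenerates_to_all_true(self):
        with pytest.warns(UserWarning):
            mask = foreground_by_kmeans(np.full((8, 8), 3.0))
        assert mask.all()

    def test_quantised_path_is_threshold_consistent(self, rng):
        # >1024 unique values exercises the binned DP; the resulting mask
        # must still be an upper level set of the intensities
        img = rng.uniform(0, 255, (64, 64)) ** 1.5
        mask = foreground_by_kmeans(img)
        assert 0 < mask.sum() < mask.size
        assert img[mask].min() >= img[~mask].max() - 255 * 1.5 / 1024


class TestBoundaryByMmd:
    def test_zero_mmd_empty_mask(self):
        params = DetectParams(mmd_threshold=3.0)
        assert not boundary_by_mmd(np.zeros((8, 8)), params).any()

    def test_single_exceedance(self):
        mmd = np.zeros((4, 4))
        mmd[2, 1] = 9.0
        mask = boundary_by_mmd(mmd, DetectParams(mmd_threshold=5.0))
        assert mask.sum() == 1 and mask[2, 1]

    def test_otsu_threshold_falls_between_bimodal_modes(self, rng):
        mmd = np.abs(
            np.concatenate(
                [rng.normal(2, 0.3, 600), rng.normal(20, 1.5, 400)]
            )
        ).reshape(40, 25)
        mask = boundary_by_mmd(mmd, DetectParams(mmd_threshold="otsu"))
        # exhaustive between-class-variance scan as the oracle
        flat = np.sort(mmd.ravel())
        best, best_t = -np.inf, None
        for t in flat[1:-1:5]:
            lo, hi = flat[flat < t], flat[flat >= t]
            var = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
            if var > best:
                best, best_t = var, t
        assert 2 < best_t < 20
        assert abs((mmd > best_t).sum() - mask.sum()) <= mmd.size * 0.02

    def test_negative_mmd_rejected(self):
        with pytest.raises(ValueError):
            boundary_by_mmd(np.full((4, 4), -1.0))


class TestCombineAndExtract:
    def test_identical_solid_disk_survives(self):
        from skimage.morphology import disk

        d = disk(10).astype(bool)
        fg = np.pad(d, 10)
        res = combine_and_extract(fg, fg, DetectParams(min_area_frac=0.001))
        assert res.area > 0
        # subtraction empties, the closed boundary restores the disk
        assert (res.mask & fg).sum() / fg.sum() > 0.95

    def test_small_speck_removed_large_block_kept(self):
        fg = np.zeros((100, 100), bool)
        fg[10:50, 10:50] = True   # 1600 px block
        fg[80:82, 80:82] = True   # 4 px speck
        bou = np.zeros_like(fg)
        res = combine_and_extract(fg, bou, DetectParams(min_area_frac=0.001))
        assert res.area == 1600
        assert not res.mask[80, 80]

    def test_translation_equivariance(self):
        fg = np.zeros((64, 64), bool)
        fg[10:30, 12:36] = True
        bou = np.zeros_like(fg)
        bou[9:31, 11:37] ^= np.pad(np.zeros((20, 24), bool), 1, constant_values=True)
        r0 = combine_and_extract(fg, bou, DetectParams(min_area_frac=0.001))
        r1 = combine_and_extract(
            np.roll(fg, (5, 7), (0, 1)), np.roll(bou, (5, 7), (0, 1)),
            DetectParams(min_area_frac=0.001),
        )
        assert r1.centroid[0] - r0.centroid[0] == pytest.approx(5.0)
        assert r1.centroid[1] - r0.centroid[1] == pytest.approx(7.0)

    def test_empty_masks_give_empty_result(self):
        res = combine_and_extract(
            np.zeros((32, 32), bool), np.zeros((32, 32), bool)
        )
        assert res.area == 0 and res.centroid is None
        assert res.orientation_deg is None

    def test_single_component_output(self, rng):
        fg = rng.random((64, 64)) > 0.7
        bou = rng.random((64, 64)) > 0.8
        res = combine_and_extract(fg, bou, DetectParams(min_area_frac=0.002))
        from skimage.measure import label

        if res.area:
            _, n = label(res.mask, connectivity=2, return_num=True)
            assert n == 1

    @pytest.mark.parametrize("angle", [15.0, 45.0, -30.0])
    def test_orientation_of_rotated_ellipse(self, angle):
        # ellipse drawn at a known angle from the x-axis (y measured up)
        rr = np.arange(96)[:, None] - 48.0
        cc = np.arange(96)[None, :] - 48.0
        th = np.deg2rad(angle)
        u = cc * np.cos(th) - rr * np.sin(th)
        v = -cc * np.sin(th) - rr * np.cos(th)
        mask = (u / 35.0) ** 2 + (v / 12.0) ** 2 <= 1.0
        res = combine_and_extract(mask, np.zeros_like(mask),
                                  DetectParams(min_area_frac=0.001))
        assert res.orientation_deg == pytest.approx(angle, abs=1.0)

    def test_orientation_of_axis_aligned_rectangles(self):
        horiz = np.zeros((64, 64), bool)
        horiz[30:34, 10:54] = True
        res = combine_and_extract(horiz, np.zeros_like(horiz),
                                  DetectParams(min_area_frac=0.001))
        assert res.orientation_deg == pytest.approx(0.0, abs=1e-6)
        vert = horiz.T.copy()
        res = combine_and_extract(vert, np.zeros_like(vert),
                                  DetectParams(min_area_frac=0.001))
        assert res.orientation_deg == pytest.approx(90.0, abs=1e-6)
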