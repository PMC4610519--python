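"""Undecimated dyadic wavelet transform: exactness and oracle checks."""

import numpy as np
import pytest

from wqiseg.wavelet import decompose, max_levels, modulus, reconstruct
from wqiseg.wavelet import _G_POS, _G_TAP, _H_POS, _H_TAP

# ---------------------------------------------------------------------------
# brute-force oracle: explicit convolution with dilated kernels, no
# filter-bank recursion, plain index arithmetic with periodic wrap


def _circular_conv(img, pos, taps, axis, dilation):
    M, N = img.shape
    out = np.zeros_like(img)
    for i in range(M):
        for j in range(N):
            acc = 0.0
            for p, t in zip(pos, taps):
                if axis == 1:
                    acc += t * img[i, (j - p * dilation) % N]
                else:
                    acc += t * img[(i - p * dilation) % M, j]
            out[i, j] = acc
    return out


def brute_force_level(img, level):
    """Detail pair and coarse at ``level`` by explicit dilated convolution."""
    s = img.copy()
    for j in range(1, level):
        d = 2 ** (j - 1)
        s = _circular_conv(
            _circular_conv(s, _H_POS, _H_TAP, 0, d), _H_POS, _H_TAP, 1, d
        )
    d = 2 ** (level - 1)
    w1 = _circular_conv(s, _G_POS, _G_TAP, 1, d)
    w2 = _circular_conv(s, _G_POS, _G_TAP, 0, d)
    coarse = _circular_conv(
        _circular_conv(s, _H_POS, _H_TAP, 0, d), _H_POS, _H_TAP, 1, d
    )
    return w1, w2, coarse


class TestDecompose:
    def test_constant_image_has_zero_details_and_constant_coarse(self):
        pyr = decompose(np.full((16, 16), 128.0), 3)
        assert np.allclose(pyr.coarse, 128.0, atol=1e-12)
        for w1, w2 in pyr.details:
            assert np.all(w1 == 0) and np.all(w2 == 0)

    def test_linearity_plane_wise(self, rng):
        f = rng.uniform(0, 255, (32, 32))
        g = rng.uniform(0, 255, (32, 32))
        a, b = 2.0, -0.7
        left = decompose(a * f + b * g, 2)
        pf, pg = decompose(f, 2), decompose(g, 2)
        assert np.abs(left.coarse - (a * pf.coarse + b * pg.coarse)).max() < 1e-10
        for (l1, l2), (f1, f2), (g1, g2) in zip(
            left.details, pf.details, pg.details
        ):
            assert np.abs(l1 - (a * f1 + b * g1)).max() < 1e-10
            assert np.abs(l2 - (a * f2 + b * g2)).max() < 1e-10

    @pytest.mark.parametrize("level", [1, 2])
    def test_matches_brute_force_convolution_oracle(self, rng, level):
        img = rng.uniform(0, 255, (16, 16))
        pyr = decompose(img, level, boundary="periodic")
        w1, w2, coarse = brute_force_level(img, level)
        assert np.abs(pyr.details[level - 1][0] - w1).max() <= 1e-10
        assert np.abs(pyr.details[level - 1][1] - w2).max() <= 1e-10
        assert np.abs(pyr.coarse - coarse).max() <= 1e-10 or level < pyr.levels

    def test_plane_count_and_shapes(self, random_image):
        pyr = decompose(random_image, 3)
        assert pyr.plane_count() == 7
        assert pyr.coarse.shape == random_image.shape
        assert all(
            w1.shape == random_image.shape and w2.shape == random_image.shape
            for w1, w2 in pyr.details
        )

    def test_too_small_image_error_names_feasible_level(self):
        with pytest.raises(ValueError, match="at most 2"):
            decompose(np.zeros((7, 64)), 3)
        assert max_levels((7, 64)) == 2

    def test_rejects_non_finite(self):
        img = np.ones((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            decompose(img, 1)


class TestReconstruct:
    @pytest.mark.parametrize("boundary", ["mirror", "periodic"])
    @pytest.mark.parametrize("levels", [1, 3])
    def test_round_trip_recovers_input(self, rng, boundary, levels):
        f = rng.uniform(0, 255, (64, 64))
        out = reconstruct(decompose(f, levels, boundary=boundary))
        assert np.abs(out - f).max() <= 1e-8

    def test_round_trip_many_random_sizes(self, rng):
        for _ in range(12):
            M = int(rng.integers(16, 96))
            N = int(rng.integers(16, 96))
            f = rng.uniform(0, 255, (M, N))
            assert np.abs(reconstruct(decompose(f, 3)) - f).max() <= 1e-8

    def test_zero_details_constant_coarse_gives_constant(self):
        pyr = decompose(np.full((32, 32), 7.0), 2, boundary="periodic")
        new = pyr.with_details(
            [(np.zeros((32, 32)), np.zeros((32, 32))) for _ in range(2)]
        )
        assert np.allclose(reconstruct(new), 7.0, atol=1e-10)

    def test_with_details_identity_keeps_exact_round_trip(self, rng):
        f = rng.uniform(0, 255, (40, 40))
        pyr = decompose(f, 3)
        same = pyr.with_details([(w1.copy(), w2.copy()) for w1, w2 in pyr.details])
        assert np.abs(reconstruct(same) - f).max() <= 1e-8

    def test_mismatched_plane_shapes_rejected(self, rng):
        pyr = decompose(rng.uniform(0, 255, (32, 32)), 2)
        with pytest.raises(ValueError):
            pyr.with_details([(np.zeros((8, 8)), np.zeros((8, 8)))] * 2)


class TestShiftCovariance:
    def test_periodic_decomposition_commutes_with_circular_shift(self, rng):
        f = rng.uniform(0, 255, (32, 32))
        shift = (5, 11)
        p1 = decompose(np.roll(f, shift, (0, 1)), 3, boundary="periodic")
        p0 = decompose(f, 3, boundary="periodic")
        assert np.array_equal(p1.coarse, np.roll(p0.coarse, shift, (0, 1)))
        for (a1, a2), (b1, b2) in zip(p1.details, p0.details):
            assert np.array_equal(a1, np.roll(b1, shift, (0, 1)))
            assert np.array_equal(a2, np.roll(b2, shift, (0, 1)))


class TestModulus:
    def test_constant_image_zero_modulus(self):
        pyr = decompose(np.full((16, 16), 50.0), 2)
        for lvl in (1, 2):
            assert np.all(modulus(pyr, lvl) == 0)

    def test_three_four_five(self, rng):
        pyr = decompose(rng.uniform(0, 255, (16, 16)), 1)
        w1, w2 = pyr.details[0]
        w1[:] = 3.0
        w2[:] = 4.0
        assert np.allclose(modulus(pyr, 1), 5.0)

    def test_equals_independent_hypot(self, random_image):
        pyr = decompose(random_image, 2)
        w1, w2 = pyr.details[1]
        assert np.abs(modulus(pyr, 2) - np.sqrt(w1**2 + w2**2)).max() <= 1e-12

    def test_level_out_of_range(self, random_image):
        pyr = decompose(random_image, 2)
        with pytest.raises(ValueError, match="out of range"):
            modulus(pyr, 3)
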