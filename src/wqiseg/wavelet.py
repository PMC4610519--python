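"""Undecimated dyadic wavelet transform (algorithme à trous).

Decomposes a grayscale image into a coarse plane ``S_J`` and per-level
horizontal/vertical detail pairs ``(W1_j, W2_j)``, all at the full image
resolution, and reconstructs exactly. The detail planes behave like smoothed
partial derivatives, so the per-pixel modulus ``sqrt(W1^2 + W2^2)`` is a
multiscale gradient-magnitude measure.

Filters are the Mallat–Zhong quadratic-spline pair (taps from the perfect
reconstruction identities ``G·K = 1 - |H|^2`` and ``L = (1 + |H|^2) / 2``),
applied separably with dilation ``2**(j-1)`` at level ``j``. Two boundary
rules are provided:

``"mirror"`` (default)
    The image is symmetrically extended once by the full analysis+synthesis
    filter support, the transform runs on the padded domain, and public planes
    are central crops. The padded planes are kept on the pyramid so the round
    trip stays exact to machine precision.
``"periodic"``
    Circular convolution on the native domain; exact and exactly
    shift-covariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WaveletPyramid", "decompose", "reconstruct", "modulus", "max_levels"]

# Quadratic-spline analysis pair (Mallat-Zhong dyadic transform):
# lowpass h, symbol H(w) = e^{iw/2} cos^3(w/2); highpass g, a forward difference.
_H_POS = (-2, -1, 0, 1)
_H_TAP = (0.125, 0.375, 0.375, 0.125)
_G_POS = (-1, 0)
_G_TAP = (1.0, -1.0)
# Synthesis filters: time-reversed lowpass, plus K = (1-|H|^2)/G and
# L = (1+|H|^2)/2 so that |Hx|^2|Hy|^2 + GxKxLy + LxGyKy = 1.
_HT_POS = (-1, 0, 1, 2)
_HT_TAP = (0.125, 0.375, 0.375, 0.125)
_K_POS = (-2, -1, 0, 1, 2, 3)
_K_TAP = (-1 / 64, -7 / 64, -22 / 64, 22 / 64, 7 / 64, 1 / 64)
_L_POS = (-3, -2, -1, 0, 1, 2, 3)
_L_TAP = (1 / 128, 6 / 128, 15 / 128, 84 / 128, 15 / 128, 6 / 128, 1 / 128)

# Half filter support consumed per level by analysis (h) and synthesis (k, l).
_ANALYSIS_RADIUS = 2
_SYNTHESIS_RADIUS = 3


def _conv1d(arr: np.ndarray, pos, taps, axis: int, dilation: int) -> np.ndarray:
    """Circular separable convolution with an integer-positioned FIR filter."""
    out = np.zeros_like(arr)
    for p, t in zip(pos, taps):
        out += t * np.roll(arr, p * dilation, axis=axis)
    return out


def max_levels(shape: tuple[int, int]) -> int:
    """Deepest decomposition level supported by an image shape.

    Level ``j`` uses filters dilated by ``2**(j-1)``; requiring
    ``2**levels <= min(M, N)`` keeps the dilated support inside the image.
    """
    return int(np.floor(np.log2(min(shape))))


@dataclass
class WaveletPyramid:
    """Undecimated dyadic wavelet representation of an image.

    Attributes
    ----------
    coarse : ndarray
        Approximation plane ``S_J`` at the input resolution.
    details : list of (ndarray, ndarray)
        Per level ``j = 1..J``, the pair ``(W1_j, W2_j)``: variation along x
        (columns) and along y (rows). Same shape as the input.
    levels : int
    boundary : str
        ``"mirror"`` or ``"periodic"``.
    """

    coarse: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray]]
    levels: int
    boundary: str = "mirror"
    # Padded planes (mirror mode) enabling an exact inverse; crops above are views.
    _pad: int = 0
    _coarse_padded: np.ndarray | None = field(default=None, repr=False)
    _details_padded: list[tuple[np.ndarray, np.ndarray]] | None = field(
        default=None, repr=False
    )

    @property
    def shape(self) -> tuple[int, int]:
        return self.coarse.shape

    def plane_count(self) -> int:
        """Number of stored planes, ``2J + 1``."""
        return 2 * self.levels + 1

    def _recentre(self, plane: np.ndarray, padded: np.ndarray | None,
                  shift: tuple[int, int]) -> np.ndarray:
        if padded is not None:
            p = self._pad
            sy, sx = shift
            M, N = self.shape
            return padded[p - sy : p - sy + M, p - sx : p - sx + N].copy()
        return np.roll(plane, shift, (0, 1))

    def centered_coarse(self) -> np.ndarray:
        """Coarse plane with the analysis group delay compensated.

        The causal spline filters delay ``S_J`` by ``(2^J - 1)/2`` pixels
        along each axis; features in the raw plane sit up-left of where they
        are in the image. This accessor shifts by the rounded delay, leaving
        at most half a pixel of residual offset — use it whenever ``S_J`` is
        consumed as a spatial field rather than fed to :func:`reconstruct`.
        """
        s = round((2**self.levels - 1) / 2)
        return self._recentre(self.coarse, self._coarse_padded, (s, s))

    def centered_details(self, level: int) -> tuple[np.ndarray, np.ndarray]:
        """Detail pair at ``level`` (1-based) with group delay compensated.

        ``W1`` (variation along x) is delayed by ``(2^j - 1)/2`` along x but
        only ``(2^(j-1) - 1)/2`` along y (no filtering on y at its own
        level); ``W2`` is the transpose case.
        """
        if not 1 <= level <= self.levels:
            raise ValueError(f"level {level} out of range 1..{self.levels}")
        long = round((2**level - 1) / 2)
        short = round((2 ** (level - 1) - 1) / 2)
        w1, w2 = self.details[level - 1]
        padded = self._details_padded[level - 1] if self._details_padded else (None, None)
        return (
            self._recentre(w1, padded[0], (short, long)),
            self._recentre(w2, padded[1], (long, short)),
        )

    def with_details(
        self, details: list[tuple[np.ndarray, np.ndarray]]
    ) -> "WaveletPyramid":
        """Return a pyramid with detail planes replaced.

        In mirror mode the padded detail planes are updated additively
        (``padded + extend(new - old)``) so that replacing a plane with itself
        leaves the exact-reconstruction path untouched.
        """
        for (w1, w2) in details:
            if w1.shape != self.shape or w2.shape != self.shape:
                raise ValueError("replacement detail planes must match pyramid shape")
        if self.boundary == "periodic" or self._details_padded is None:
            return WaveletPyramid(
                self.coarse, [(w1.copy(), w2.copy()) for w1, w2 in details],
                self.levels, self.boundary,
            )
        pad = self._pad
        new_padded = []
        for (w1, w2), (p1, p2), (o1, o2) in zip(
            details, self._details_padded, self.details
        ):
            q1 = p1 + np.pad(w1 - o1, pad, mode="symmetric")
            q2 = p2 + np.pad(w2 - o2, pad, mode="symmetric")
            new_padded.append((q1, q2))
        out = WaveletPyramid(
            self.coarse,
            [(q1[pad:-pad, pad:-pad], q2[pad:-pad, pad:-pad]) for q1, q2 in new_padded],
            self.levels,
            self.boundary,
            _pad=pad,
            _coarse_padded=self._coarse_padded,
            _details_padded=new_padded,
        )
        return out


def _pad_width(levels: int) -> int:
    return (_ANALYSIS_RADIUS + _SYNTHESIS_RADIUS) * (2**levels - 1)


def _analyse(s: np.ndarray, levels: int):
    details = []
    for j in range(1, levels + 1):
        d = 2 ** (j - 1)
        w1 = _conv1d(s, _G_POS, _G_TAP, axis=1, dilation=d)
        w2 = _conv1d(s, _G_POS, _G_TAP, axis=0, dilation=d)
        s = _conv1d(
            _conv1d(s, _H_POS, _H_TAP, axis=0, dilation=d),
            _H_POS, _H_TAP, axis=1, dilation=d,
        )
        details.append((w1, w2))
    return s, details


def _synthesise(s: np.ndarray, details) -> np.ndarray:
    for j in range(len(details), 0, -1):
        d = 2 ** (j - 1)
        w1, w2 = details[j - 1]
        s = (
            _conv1d(
                _conv1d(s, _HT_POS, _HT_TAP, axis=0, dilation=d),
                _HT_POS, _HT_TAP, axis=1, dilation=d,
            )
            + _conv1d(
                _conv1d(w1, _K_POS, _K_TAP, axis=1, dilation=d),
                _L_POS, _L_TAP, axis=0, dilation=d,
            )
            + _conv1d(
                _conv1d(w2, _K_POS, _K_TAP, axis=0, dilation=d),
                _L_POS, _L_TAP, axis=1, dilation=d,
            )
        )
    return s


def decompose(
    image: np.ndarray, levels: int, boundary: str = "mirror"
) -> WaveletPyramid:
    """Undecimated dyadic wavelet analysis to ``levels`` scales.

    Parameters
    ----------
    image : 2-D array
        Grayscale intensity field; finite values.
    levels : int
        Number of dyadic scales ``J >= 1``.
    boundary : {"mirror", "periodic"}

    Returns
    -------
    WaveletPyramid
        Coarse plane plus ``levels`` detail pairs, all input-sized. The map is
        linear: ``decompose(a*f + b*g)`` equals the plane-wise combination.

    Raises
    ------
    ValueError
        If the image is too small for the requested depth; the message names
        the deepest feasible level.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    feasible = max_levels(image.shape)
    if levels > feasible:
        raise ValueError(
            f"image of shape {image.shape} supports at most {feasible} "
            f"decomposition levels (requested {levels}): the dilated filter "
            "support would exceed the image"
        )
    if boundary not in ("mirror", "periodic"):
        raise ValueError(f"unknown boundary rule {boundary!r}")

    if boundary == "periodic":
        coarse, details = _analyse(image, levels)
        return WaveletPyramid(coarse, details, levels, boundary)

    pad = _pad_width(levels)
    padded = np.pad(image, pad, mode="symmetric")
    coarse_p, details_p = _analyse(padded, levels)
    crop = (slice(pad, -pad), slice(pad, -pad))
    return WaveletPyramid(
        coarse_p[crop],
        [(w1[crop], w2[crop]) for w1, w2 in details_p],
        levels,
        boundary,
        _pad=pad,
        _coarse_padded=coarse_p,
        _details_padded=details_p,
    )


def reconstruct(pyramid: WaveletPyramid) -> np.ndarray:
    """Inverse undecimated dyadic wavelet transform.

    Recovers ``S_0`` level by level; for an unmodified pyramid the round trip
    ``reconstruct(decompose(f, J))`` returns ``f`` to machine precision under
    either boundary rule. Pyramids with replaced detail planes reconstruct
    with the same recursion (mirror mode re-extends the edits symmetrically).
    """
    shape = pyramid.shape
    for w1, w2 in pyramid.details:
        if w1.shape != shape or w2.shape != shape:
            raise ValueError("pyramid planes have inconsistent shapes")
    if pyramid.boundary == "periodic" or pyramid._coarse_padded is None:
        if pyramid.boundary == "periodic":
            return _synthesise(pyramid.coarse, pyramid.details)
        pad = _pad_width(pyramid.levels)
        coarse = np.pad(pyramid.coarse, pad, mode="symmetric")
        details = [
            (np.pad(w1, pad, mode="symmetric"), np.pad(w2, pad, mode="symmetric"))
            for w1, w2 in pyramid.details
        ]
        return _synthesise(coarse, details)[pad:-pad, pad:-pad]
    pad = pyramid._pad
    out = _synthesise(pyramid._coarse_padded, pyramid._details_padded)
    return out[pad:-pad, pad:-pad]


def modulus(pyramid: WaveletPyramid, level: int) -> np.ndarray:
    """Wavelet modulus ``sqrt(W1^2 + W2^2)`` at a given level (1-based)."""
    if not 1 <= level <= pyramid.levels:
        raise ValueError(
            f"level {level} out of range 1..{pyramid.levels}"
        )
    w1, w2 = pyramid.details[level - 1]
    return np.hypot(w1, w2)
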