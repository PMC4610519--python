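"""Local texture-difference measures between two frames.

All measures live on the level-J wavelet detail pair, treated as a smoothed
gradient vector per pixel: they respond to changes in local gray-level
*arrangement* rather than in absolute brightness, which is what makes them
robust to illumination switches.

- MMD: absolute difference of the wavelet moduli of the two frames.
- CC: signed dot product of the two gradient vectors, ``M1·M2·cos(theta)``.
- TDR: ``1 - 2·ΣCC / Σ(M1² + M2²)`` summed over the 3×3 neighbourhood; 0
  when the local texture is unchanged, up to 2 for opposed gradients, and in
  [0, 2] always (AM–GM).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

from .wavelet import WaveletPyramid

__all__ = ["gradient_planes", "mmd_map", "tdr_map"]


def gradient_planes(pyramid: WaveletPyramid) -> tuple[np.ndarray, np.ndarray]:
    """Level-J detail pair ``(W1_J, W2_J)`` viewed as a per-pixel gradient.

    Returned with the analysis group delay compensated, so the gradient at
    index ``(i, j)`` describes the image around that same pixel — required
    for the texture measures to localise boundaries where they actually are.
    """
    if not pyramid.details:
        raise ValueError("pyramid has no detail levels")
    return pyramid.centered_details(pyramid.levels)


def _check_compatible(p1: WaveletPyramid, p2: WaveletPyramid):
    if p1.shape != p2.shape or p1.levels != p2.levels:
        raise ValueError("pyramids must share shape and decomposition depth")


def mmd_map(pyr1: WaveletPyramid, pyr2: WaveletPyramid) -> np.ndarray:
    """Modulus-magnitude difference ``|M_J f1 - M_J f2|`` (symmetric, >= 0),
    computed on the delay-compensated detail pairs."""
    _check_compatible(pyr1, pyr2)
    m1 = np.hypot(*gradient_planes(pyr1))
    m2 = np.hypot(*gradient_planes(pyr2))
    return np.abs(m1 - m2)


def tdr_map(pyr1: WaveletPyramid, pyr2: WaveletPyramid) -> np.ndarray:
    """Texture difference rate over 3×3 neighbourhoods (mirror-padded).

    Where both frames are locally textureless the denominator vanishes and
    the TDR is defined as 0 (no texture, no texture change) — the
    conservative choice for the downstream contrast gain.
    """
    _check_compatible(pyr1, pyr2)
    a1, a2 = gradient_planes(pyr1)
    b1, b2 = gradient_planes(pyr2)
    cc = a1 * b1 + a2 * b2
    sq = a1 * a1 + a2 * a2 + b1 * b1 + b2 * b2
    # 3x3 box sums; uniform_filter "reflect" = symmetric padding
    num = uniform_filter(cc, size=3, mode="reflect") * 9.0
    den = uniform_filter(sq, size=3, mode="reflect") * 9.0
    out = np.zeros_like(num)
    nz = den > 0
    out[nz] = 1.0 - 2.0 * num[nz] / den[nz]
    return out
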