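"""Quotient-image reflectance estimators.

The wavelet-quotient image (WQI) divides an anisotropically diffused copy of
the image by the coarse plane ``S_J`` of its undecimated dyadic wavelet
transform: numerator keeps edges (feature-preserving smoother), denominator
carries the low-frequency illumination, so the quotient approximates the
reflectance up to a smooth factor. The self-quotient image (SQI) — image over
its own Gaussian blur — is the classical comparator.

Both quotients are homogeneous of degree zero: scaling the input intensities
leaves them unchanged (the epsilon guard scales with the image).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .diffusion import DiffusionParams, perona_malik
from .wavelet import decompose

__all__ = ["ReflectanceMap", "diffuse_canonical", "wavelet_quotient", "self_quotient"]


@dataclass
class ReflectanceMap:
    """Dimensionless reflectance quotient ``values`` (>= 0) with the epsilon
    used to guard the division."""

    values: np.ndarray
    epsilon: float

    @property
    def shape(self):
        return self.values.shape


def _relative_epsilon(image: np.ndarray, epsilon: float | None) -> float:
    if epsilon is not None:
        if epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        return float(epsilon)
    return 1e-6 * float(max(np.max(image, initial=0.0), 1.0))


def diffuse_canonical(image: np.ndarray, params: DiffusionParams | None) -> np.ndarray:
    """Perona–Malik smoothing on a canonical 0–255 intensity scale.

    The conductance scale ``kappa`` is an absolute intensity, so diffusion is
    not homogeneous under global rescaling; normalising to the canonical
    range first (and scaling back) restores degree-1 homogeneity, which the
    quotient needs to be invariant to global intensity scaling.
    """
    image = np.asarray(image, dtype=float)
    peak = float(np.max(np.abs(image), initial=0.0))
    if peak == 0:
        return image.copy()
    c = 255.0 / peak
    return perona_malik(c * image, params) / c


def wavelet_quotient(
    image: np.ndarray,
    levels: int = 3,
    diffusion: DiffusionParams | None = None,
    epsilon: float | None = None,
    boundary: str = "mirror",
) -> ReflectanceMap:
    """Wavelet-quotient image ``Diffuse(f) / S_J(f)``.

    The denominator is clamped below at ``epsilon`` (default ``1e-6`` of the
    image maximum, which keeps the quotient scale-invariant). An all-zero
    image maps to an all-zero quotient.
    """
    image = np.asarray(image, dtype=float)
    eps = _relative_epsilon(image, epsilon)
    num = diffuse_canonical(image, diffusion)
    coarse = decompose(image, levels, boundary=boundary).centered_coarse()
    return ReflectanceMap(num / np.maximum(coarse, eps), eps)


def self_quotient(
    image: np.ndarray, sigma: float = 8.0, epsilon: float | None = None
) -> ReflectanceMap:
    """Self-quotient image ``f / (G_sigma * f)`` with the same epsilon guard."""
    image = np.asarray(image, dtype=float)
    eps = _relative_epsilon(image, epsilon)
    smooth = gaussian_filter(image, sigma, mode="reflect")
    return ReflectanceMap(image / np.maximum(smooth, eps), eps)
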