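"""Virtual-image synthesis.

Builds the image actually segmented: the illumination difference between the
current and reference frames, amplified where the local texture changed
(TDR above a threshold — i.e., where a foreground object sits), is
exponentiated and re-attached to the current frame's reflectance. Background
pixels see only the un-amplified lighting change, foreground pixels see the
doubled log-difference, so foreground ends up markedly brighter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quotient import ReflectanceMap

__all__ = ["SynthesisParams", "mapping", "synthesize"]

# log-domain clip before exponentiation; far outside any 8-bit dynamic range
_MAPPING_CLIP = 50.0


@dataclass
class SynthesisParams:
    """gain: contrast factor c > 1 applied where texture changed (default 2);
    tdr_threshold: TDR level gamma above which a pixel counts as texture-
    changed (default 0.5); strict_literal: evaluate the mapping as
    ``alpha*Ic - Ir`` instead of ``alpha*(Ic - Ir)`` (the literal reading of
    an ambiguously typeset definition; off by default)."""

    gain: float = 2.0
    tdr_threshold: float = 0.5
    strict_literal: bool = False

    def __post_init__(self):
        if self.gain <= 1:
            raise ValueError("gain must be > 1")
        if not 0 < self.tdr_threshold < 2:
            raise ValueError("tdr_threshold must lie in (0, 2)")


def mapping(
    illum_current: np.ndarray,
    illum_reference: np.ndarray,
    tdr: np.ndarray,
    params: SynthesisParams | None = None,
) -> np.ndarray:
    """Gated log-illumination difference ``alpha · (Ĩc - Ĩr)``.

    ``alpha = gain`` where ``tdr > tdr_threshold`` (texture changed,
    foreground candidate) and 1 elsewhere.
    """
    params = params or SynthesisParams()
    ic = np.asarray(illum_current, dtype=float)
    ir = np.asarray(illum_reference, dtype=float)
    tdr = np.asarray(tdr, dtype=float)
    if ic.shape != ir.shape or ic.shape != tdr.shape:
        raise ValueError("illumination and TDR grids must share one shape")
    alpha = np.where(tdr > params.tdr_threshold, params.gain, 1.0)
    if params.strict_literal:
        return alpha * ic - ir
    return alpha * (ic - ir)


def synthesize(
    illum_current: np.ndarray,
    illum_reference: np.ndarray,
    reflectance: ReflectanceMap | np.ndarray,
    tdr: np.ndarray,
    params: SynthesisParams | None = None,
) -> np.ndarray:
    """Synthesized virtual image ``exp(mapping + log(r̃ + 1)) - 1``.

    The reflectance enters through the same unit-offset log used throughout,
    so a zero mapping returns the reflectance unchanged; the mapping is
    clipped to ±50 in log space to keep the exponential finite.
    """
    params = params or SynthesisParams()
    refl = reflectance.values if isinstance(reflectance, ReflectanceMap) else reflectance
    refl = np.asarray(refl, dtype=float)
    if np.any(refl < 0):
        raise ValueError("reflectance must be non-negative")
    m = mapping(illum_current, illum_reference, tdr, params)
    if m.shape != refl.shape:
        raise ValueError("reflectance shape mismatch")
    m = np.clip(m, -_MAPPING_CLIP, _MAPPING_CLIP)
    return np.expm1(m + np.log1p(refl))
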