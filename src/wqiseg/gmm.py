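"""Adaptive Gaussian-mixture background subtraction (comparator).

Per-pixel mixture of ``K`` Gaussians maintained online in the
Stauffer–Grimson fashion: each incoming intensity either updates the first
component it matches (within 2.5 sigma) or replaces the least-supported one;
components are ranked by weight/sigma and the top-ranked ones holding a
cumulative weight ``background_ratio`` form the background model. A pixel
matching no background component is foreground.

This is the standard baseline that breaks under sudden global illumination
changes — every pixel departs from its background model at once — which is
exactly the failure mode the synthesized-image pipeline is designed to
avoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GmmParams", "GaussianMixtureBackground", "run_gmm_baseline"]


@dataclass
class GmmParams:
    n_components: int = 3
    learning_rate: float = 0.01
    match_sigmas: float = 2.5
    background_ratio: float = 0.7
    initial_variance: float = 225.0  # (15 intensity levels)^2
    min_variance: float = 4.0


class GaussianMixtureBackground:
    """Online per-pixel Gaussian mixture background model."""

    def __init__(self, shape: tuple[int, int], params: GmmParams | None = None):
        self.params = params or GmmParams()
        K = self.params.n_components
        self.weight = np.zeros((K,) + shape)
        self.mean = np.zeros((K,) + shape)
        self.var = np.full((K,) + shape, self.params.initial_variance)
        self.weight[0] = 1.0
        self._initialised = False

    def apply(self, frame: np.ndarray) -> np.ndarray:
        """Update the model with one frame; return its foreground mask."""
        p = self.params
        x = np.asarray(frame, dtype=float)
        if not self._initialised:
            self.mean[0] = x
            self._initialised = True
            return np.zeros(x.shape, dtype=bool)

        diff = x[None] - self.mean
        d2 = diff * diff
        matched = d2 < (p.match_sigmas**2) * self.var
        # first matching component in rank order (weight/sigma descending)
        rank = self.weight / np.sqrt(self.var)
        order = np.argsort(-rank, axis=0)
        matched_ranked = np.take_along_axis(matched, order, axis=0)
        first_rank_pos = np.argmax(matched_ranked, axis=0)
        any_match = matched_ranked.any(axis=0)
        win = np.take_along_axis(
            order, first_rank_pos[None], axis=0
        )[0]  # component index that wins, valid where any_match

        K = p.n_components
        comp_idx = np.arange(K).reshape(K, 1, 1)
        is_winner = (comp_idx == win[None]) & any_match[None]

        # weight update: w <- (1-a) w + a * ownership
        self.weight = (1 - p.learning_rate) * self.weight + p.learning_rate * is_winner
        # matched component mean/var update with rho = a * N(x|mu,var) surrogate
        rho = p.learning_rate
        self.mean = np.where(is_winner, self.mean + rho * diff, self.mean)
        self.var = np.where(
            is_winner,
            np.maximum(self.var + rho * (d2 - self.var), p.min_variance),
            self.var,
        )
        # unmatched pixels: replace weakest component
        weakest = np.argmin(self.weight, axis=0)
        replace = (comp_idx == weakest[None]) & (~any_match[None])
        self.mean = np.where(replace, x[None], self.mean)
        self.var = np.where(replace, p.initial_variance, self.var)
        self.weight = np.where(replace, 0.05, self.weight)
        self.weight /= self.weight.sum(axis=0, keepdims=True)

        # background set: top-ranked components up to cumulative weight
        bg = self._background_components()
        fg_match = matched & bg
        return ~fg_match.any(axis=0)

    def _background_components(self) -> np.ndarray:
        p = self.params
        rank = self.weight / np.sqrt(self.var)
        order = np.argsort(-rank, axis=0)
        w_sorted = np.take_along_axis(self.weight, order, axis=0)
        cum = np.cumsum(w_sorted, axis=0)
        bg_sorted = cum - w_sorted < p.background_ratio
        bg = np.zeros_like(bg_sorted)
        np.put_along_axis(bg, order, bg_sorted, axis=0)
        return bg

    def distance(self, frame: np.ndarray) -> np.ndarray:
        """Per-pixel foreground score: Mahalanobis distance of the intensity
        to the closest *background* component (continuous analogue of the
        binary mask, usable as a ROC score). Call before :meth:`apply`."""
        x = np.asarray(frame, dtype=float)
        d = np.abs(x[None] - self.mean) / np.sqrt(self.var)
        bg = self._background_components()
        d = np.where(bg, d, np.inf)
        return d.min(axis=0)


def run_gmm_baseline(
    frames, history: int, params: GmmParams | None = None
) -> list[np.ndarray]:
    """Warm the mixture model on ``history`` frames, then return one raw
    foreground mask per remaining frame (no morphological post-processing —
    the caller combines them exactly as the primary pipeline's masks are)."""
    frames = list(frames)
    if len(frames) < history:
        raise ValueError(
            f"need at least history={history} frames, got {len(frames)}"
        )
    if history < 1:
        raise ValueError("history must be >= 1")
    model = GaussianMixtureBackground(np.asarray(frames[0]).shape, params)
    for f in frames[:history]:
        model.apply(f)
    return [model.apply(f) for f in frames[history:]]
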