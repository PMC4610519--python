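"""Synthetic farrowing-pen scenes with known ground truth.

Every frame is built generatively from the illumination–reflectance model
``f = clip(i · r + noise, 0, 255)``:

- ``r`` (reflectance): a straw-textured floor (Gaussian-smoothed seeded
  noise), optionally re-shuffled patch-wise per frame (straw dragged around
  — dynamic background); a large bright textured ellipse (the sow), which
  may move, stay motionless, or — in the stress variant — carry
  background-matched texture (a dirty sow); and small bright blobs
  (piglets).
- ``i`` (illumination): a smooth multiplicative field (uniform, ramp or
  spot) carrying the intensity scale, stepped by "lamp events" (lights
  switched on/off) that multiply the illumination only. Reflectance is
  dimensionless around 1, so ``true_illum`` is the quantity an illumination
  estimator should recover.

The generator therefore hands every stage its own ground truth: the true
illumination and reflectance fields and the exact foreground masks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["AnimalSpec", "PigletSpec", "SceneSpec", "SceneFrame", "Scene", "generate"]


@dataclass
class AnimalSpec:
    """Sow-like ellipse: ``center`` (row, col) at frame 0, per-frame
    ``velocity`` (rows, cols), semi-``axes`` (a, b) in pixels, orientation in
    degrees from the x-axis, mean reflectance ``base`` and texture
    amplitude/correlation length."""

    center: tuple[float, float] = (128.0, 128.0)
    velocity: tuple[float, float] = (0.0, 0.0)
    axes: tuple[float, float] = (80.0, 40.0)
    orientation_deg: float = 20.0
    base: float = 1.9
    texture_amplitude: float = 0.25
    texture_scale: float = 3.0


@dataclass
class PigletSpec:
    center: tuple[float, float] = (60.0, 200.0)
    velocity: tuple[float, float] = (0.0, 0.0)
    radius: float = 9.0
    base: float = 1.65
    texture_amplitude: float = 0.18
    texture_scale: float = 2.0


@dataclass
class SceneSpec:
    """Scene recipe; ``seed`` fixes the full sequence byte-exactly.

    ``lamp_events`` are (frame, gain) multiplicative illumination steps that
    persist from their frame onward. ``n_reference`` frames are generated
    without any foreground (the warm-up segment for background models);
    frame 0 of that segment is the pipeline's reference image.
    """

    size: tuple[int, int] = (256, 256)
    n_frames: int = 30
    n_reference: int = 64
    illumination_field: str = "ramp"  # uniform | ramp | spot
    illumination_amplitude: float = 0.3
    illumination_level: float = 80.0  # lamp intensity over unit reflectance
    lamp_events: list[tuple[int, float]] = field(default_factory=list)
    animal: AnimalSpec | None = field(default_factory=AnimalSpec)
    piglets: list[PigletSpec] = field(default_factory=list)
    background_base: float = 1.0
    background_texture_amplitude: float = 0.08
    background_texture_scale: float = 2.0
    straw_dynamics: float = 0.0  # fraction of 16x16 patches reshuffled/frame
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(g <= 0 for _, g in self.lamp_events):
            raise ValueError("lamp gains must be > 0")
        if self.illumination_field not in ("uniform", "ramp", "spot"):
            raise ValueError("unknown illumination field")
        if self.animal is not None:
            M, N = self.size
            r, c = self.animal.center
            if not (0 <= r < M and 0 <= c < N):
                raise ValueError("animal centre must start inside the frame")


@dataclass
class SceneFrame:
    image: np.ndarray
    true_illum: np.ndarray
    true_refl: np.ndarray
    animal_mask: np.ndarray
    piglet_mask: np.ndarray
    event_flag: bool


@dataclass
class Scene:
    spec: SceneSpec
    reference: SceneFrame
    warmup: list[SceneFrame]
    frames: list[SceneFrame]

    def manifest(self) -> str:
        d = asdict(self.spec)
        d["n_warmup"] = len(self.warmup)
        return json.dumps(d, indent=2)


def _texture(rng, shape, base, amplitude, scale):
    noise = gaussian_filter(rng.standard_normal(shape), scale, mode="wrap")
    sd = noise.std()
    if sd > 0:
        noise /= sd
    return base + amplitude * noise


def _ellipse_mask(shape, center, axes, orientation_deg):
    M, N = shape
    rr = np.arange(M)[:, None] - center[0]
    cc = np.arange(N)[None, :] - center[1]
    # x along columns, y up; rotate into the ellipse frame
    th = np.deg2rad(orientation_deg)
    x, y = cc, -rr
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _illumination(spec: SceneSpec) -> np.ndarray:
    M, N = spec.size
    amp = spec.illumination_amplitude
    if spec.illumination_field == "uniform":
        base = np.ones((M, N))
    elif spec.illumination_field == "ramp":
        base = 1.0 + amp * (np.arange(N)[None, :] / max(N - 1, 1) - 0.5)
        base = np.repeat(base, M, axis=0)
    else:  # spot: bright pool under a lamp
        rr = (np.arange(M)[:, None] - M / 3) / (0.4 * M)
        cc = (np.arange(N)[None, :] - N / 2) / (0.4 * N)
        base = 1.0 + amp * np.exp(-(rr**2 + cc**2))
    return spec.illumination_level * base


def generate(spec: SceneSpec) -> Scene:
    """Generate the reference segment and the animal segment of a scene."""
    rng = np.random.default_rng(spec.seed)
    M, N = spec.size
    straw = _texture(
        rng, (M, N), spec.background_base,
        spec.background_texture_amplitude, spec.background_texture_scale,
    )
    illum0 = _illumination(spec)
    animal_tex = (
        _texture(
            rng, (M, N), spec.animal.base,
            spec.animal.texture_amplitude, spec.animal.texture_scale,
        )
        if spec.animal is not None
        else None
    )
    piglet_tex = [
        _texture(rng, (M, N), p.base, p.texture_amplitude, p.texture_scale)
        for p in spec.piglets
    ]

    # feathered blend: dragged straw has no crisp rectangular boundary
    patch = 16
    feather = np.ones((patch, patch))
    feather = gaussian_filter(np.pad(feather, patch // 2), 3.0)[
        patch // 2 : -patch // 2, patch // 2 : -patch // 2
    ]

    def shuffle_straw(refl, frame_rng):
        if spec.straw_dynamics <= 0:
            return refl
        out = refl.copy()
        nr, nc = M // patch, N // patch
        n_shuffle = int(round(spec.straw_dynamics * nr * nc))
        for _ in range(n_shuffle):
            i = frame_rng.integers(nr) * patch
            j = frame_rng.integers(nc) * patch
            block = _texture(
                frame_rng, (patch, patch), spec.background_base,
                spec.background_texture_amplitude, spec.background_texture_scale,
            )
            sl = (slice(i, i + patch), slice(j, j + patch))
            out[sl] = (1 - feather) * out[sl] + feather * block
        return out

    def build_frame(t, with_foreground, straw_field, gain, event_flag):
        refl = straw_field.copy()
        animal_mask = np.zeros((M, N), dtype=bool)
        piglet_mask = np.zeros((M, N), dtype=bool)
        if with_foreground and spec.animal is not None:
            a = spec.animal
            center = (a.center[0] + a.velocity[0] * t, a.center[1] + a.velocity[1] * t)
            animal_mask = _ellipse_mask((M, N), center, a.axes, a.orientation_deg)
            refl[animal_mask] = animal_tex[animal_mask]
        if with_foreground:
            for p, tex in zip(spec.piglets, piglet_tex):
                center = (p.center[0] + p.velocity[0] * t, p.center[1] + p.velocity[1] * t)
                m = _ellipse_mask((M, N), center, (p.radius, p.radius), 0.0)
                m &= ~animal_mask
                refl[m] = tex[m]
                piglet_mask |= m
        illum = illum0 * gain
        noise = (
            spec.noise_sigma * rng.standard_normal((M, N))
            if spec.noise_sigma > 0
            else 0.0
        )
        image = np.clip(illum * refl + noise, 0.0, 255.0)
        return SceneFrame(image, illum, refl, animal_mask, piglet_mask, event_flag)

    warmup = []
    straw_field = straw
    for t in range(spec.n_reference):
        frame_rng = np.random.default_rng(rng.integers(2**31))
        straw_field = shuffle_straw(straw_field, frame_rng)
        warmup.append(build_frame(t, False, straw_field, 1.0, False))
    # the reference is the background state right before the animals enter
    reference = build_frame(0, False, straw_field, 1.0, False)
    frames = []
    for t in range(spec.n_frames):
        frame_rng = np.random.default_rng(rng.integers(2**31))
        straw_field = shuffle_straw(straw_field, frame_rng)
        gain = 1.0
        event_flag = False
        for ev_frame, ev_gain in spec.lamp_events:
            if t >= ev_frame:
                gain *= ev_gain
            if t == ev_frame:
                event_flag = True
        frames.append(build_frame(t, True, straw_field, gain, event_flag))
    return Scene(spec, reference, warmup, frames)
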