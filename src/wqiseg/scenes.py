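"""Canned study conditions for the synthetic generator.

One place defines the scene recipes every test and evaluation run uses, so
"a lamp-step scene" means the same thing everywhere:

- ``static``: sow present and motionless from the first frame, steady light.
- ``moving``: sow drifts across the pen, steady light, mild straw dynamics.
- ``lamp_step``: sow moves while the lamps switch (off to half, later back
  up), the scenario that defeats per-pixel background models.
- ``motionless``: 50 identical-pose frames, the long-motionless-sow claim.
- ``dirty_sow``: stress variant with the sow's texture matched to the straw
  (caked mud), the documented failure mode of texture-gated synthesis.

Light-on scenes start from a lower base level so a 1.8× lamp gain stays
inside the 8-bit range.
"""

from __future__ import annotations

from .synthgen import AnimalSpec, PigletSpec, SceneSpec

__all__ = ["study_scene"]


def study_scene(kind: str, seed: int = 0, size: int = 256,
                n_frames: int | None = None) -> SceneSpec:
    """Scene recipe for one of the named study conditions."""
    animal = AnimalSpec(
        center=(size * 0.5, size * 0.42),
        axes=(size * 0.31, size * 0.155),
        orientation_deg=15.0,
    )
    # piglets roam the corners without touching the sow: the sow-only
    # overlap score is only well defined while the animals stay separated
    piglets = [
        PigletSpec(center=(size * 0.22, size * 0.78), velocity=(0.15, 0.15)),
        PigletSpec(center=(size * 0.8, size * 0.2), velocity=(-0.15, 0.2),
                   radius=8.0),
    ]
    common = dict(size=(size, size), seed=seed, piglets=piglets,
                  straw_dynamics=0.005)
    if kind == "static":
        return SceneSpec(n_frames=n_frames or 20, animal=animal, **common)
    if kind == "moving":
        animal.velocity = (0.3, 0.9)
        return SceneSpec(n_frames=n_frames or 20, animal=animal, **common)
    if kind == "lamp_step":
        animal.velocity = (0.3, 0.9)
        n = n_frames or 20
        return SceneSpec(
            n_frames=n, animal=animal,
            illumination_level=55.0,
            lamp_events=[(n // 3, 0.5), (2 * n // 3, 3.0)],
            **common,
        )
    if kind == "motionless":
        return SceneSpec(n_frames=n_frames or 50, animal=animal, **common)
    if kind == "dirty_sow":
        animal.base = 1.02
        animal.texture_amplitude = 0.08
        animal.texture_scale = 2.0
        animal.velocity = (0.3, 0.9)
        return SceneSpec(n_frames=n_frames or 20, animal=animal, **common)
    raise ValueError(f"unknown scene kind {kind!r}")
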