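# wqiseg

Illumination/reflectance estimation and illumination-invariant foreground
detection for grayscale image sequences.

The motivating application is video monitoring of sows in farrowing pens:
scenes where ceiling lamps switch on and off without warning (sudden global
illumination changes), the animal can lie still for long stretches
(motionless foreground), and straw bedding is dragged around (dynamic
background). Classical per-pixel background models collapse under the lamp
switches; this package segments the animal anyway by separating what the
camera sees into lighting and material factors.

## Method

Every frame is modelled multiplicatively, `f(x,y) = i(x,y) · r(x,y)`, with a
slowly varying illumination field `i` and a material/reflectance field `r`.
Two estimators, both built on an undecimated dyadic (à-trous) wavelet
transform with the quadratic-spline filter pair, factor a frame:

- **Homomorphic wavelet filter (HWF).** In log space `log f = log i + log r`.
  The log image is decomposed into a coarse plane `S_J` and detail planes
  `{W¹_j, W²_j}`; the details are attenuated by a Butterworth high-pass gain
  `H(u,v) = 1 / (1 + (D0/D)^{2n})` and the transform inverted, leaving the
  smooth log-illumination estimate `Ĩ`.
- **Wavelet-quotient image (WQI).** `WQI = Diffuse(f) / S_J(f)`: a
  Perona–Malik–smoothed copy of the frame divided by its own coarse plane, a
  reflectance estimate that is invariant to global intensity scaling.

Detection compares the current frame `c` against a fixed animal-free
reference frame `r`:

1. texture change per pixel via the level-J detail pair treated as a
   gradient: the modulus difference `MMD = |M_J f_c − M_J f_r|` and the
   normalized 3×3 texture-difference rate `TDR ∈ [0, 2]` (≈0 where local
   texture is unchanged — in particular under pure lighting changes);
2. a synthesized virtual image
   `f_syn = exp(α·(Ĩ_c − Ĩ_r) + log(r̃_c + 1)) − 1`, with `α = c > 1` where
   `TDR > γ` (texture changed, i.e. foreground) and 1 elsewhere — foreground
   comes out several times brighter than background regardless of lamp
   state;
3. exact 1-D k-means (k = 3) on the synthesized intensities — the brightest
   cluster is the foreground candidate — plus an MMD boundary mask, combined
   by morphological closing, subtraction (separating piglet-scale blobs,
   which are then removed by size), union, largest-component selection and
   hole filling, yielding the animal mask with its area, centroid and
   ellipse orientation.

A hand-written Stauffer–Grimson adaptive Gaussian-mixture background model
is included purely as the comparison baseline, and a seeded synthetic-scene
generator (`wqiseg.synthgen`) produces farrowing-pen-like sequences with
exact ground truth (true `i`, true `r`, animal/piglet masks, lamp-event
schedule) so every stage is testable without recorded video.

## Worked example

```python
import wqiseg as w

# a 256x256 pen: textured straw floor, a walking sow, two piglets,
# lamps dimming to 50% at frame 6 and back up 3x at frame 13
spec = w.study_scene("lamp_step", seed=1, n_frames=20)
scene = w.generate(spec)

outs = w.run_frames(scene.reference.image,
                    [f.image for f in scene.frames])
for t in (5, 6, 13):
    det = outs[t].detection
    score = w.iou(det.mask, scene.frames[t].animal_mask)
    print(f"frame {t:2d} event={scene.frames[t].event_flag!s:5} "
          f"area={det.area:5d} centroid=({det.centroid[0]:5.1f},"
          f"{det.centroid[1]:5.1f}) orient={det.orientation_deg:6.1f}deg "
          f"IoU={score:.3f}")
```

prints (exactly, for this seed):

```
frame  5 event=False area= 9536 centroid=(127.6,116.3) orient=  11.6deg IoU=0.875
frame  6 event=True  area= 9985 centroid=(129.5,114.2) orient=  13.8deg IoU=0.940
frame 13 event=True  area=10373 centroid=(132.4,119.6) orient=  14.8deg IoU=0.953
```

Frame 6 is the instant the lamps drop to half intensity and frame 13 the
instant they triple: the detected area, centroid and orientation stay
consistent with the no-event frame 5, and the overlap with the true sow mask
stays around 0.9 — the detection does not notice the lamp. The orientation
is the angle between the image x-axis and the sow ellipse's major axis
(truth: 15°).

The same pipeline is available from the shell:

```
wqiseg synthgen --output-dir scene --seed 1 --n-frames 20 --lamp-event 6:0.5
wqiseg run --input-dir scene/frames --output-dir out --reference scene/frames/reference.png
wqiseg eval --pred-dir out --truth-dir scene/truth
```

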