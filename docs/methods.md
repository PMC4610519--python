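# Methods

This note records the model, the numerical choices and the known limits of
the package. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Image model

A grayscale frame is modelled as `f(x,y) = i(x,y) · r(x,y) (+ noise)`:
`i` is the illumination field (smooth in space; it carries the intensity
scale and all lamp switching) and `r` the reflectance/material field
(dimensionless, order 1, carrying texture and object structure). The
factorisation is only defined up to a scalar; the package's convention is
`r ≈ 1` over generic background so that `i` has intensity units.

## Undecimated dyadic wavelet transform

All multiscale structure comes from one transform: the à-trous filter bank
with the quadratic-spline analysis pair

- lowpass `h = [1, 3, 3, 1]/8` at taps −2..1 (symbol `e^{iω/2} cos³(ω/2)`),
- highpass `g = [1, −1]` at taps −1..0 (a forward difference, so detail
  planes behave like smoothed partial derivatives),

dilated by `2^(j−1)` at level `j` and applied separably: `W¹_j` filters
along x (columns) only, `W²_j` along y, the coarse `S_j` along both. The
synthesis filters are derived from the exact perfect-reconstruction
identities `G·K = 1 − |H|²` and `L = (1 + |H|²)/2`, giving
`k = [−1, −7, −22, 22, 7, 1]/64` and `l = [1, 6, 15, 84, 15, 6, 1]/128`;
with these, `|H_x|²|H_y|² + G_xK_xL_y + L_xG_yK_y ≡ 1` and the round trip is
exact to floating-point rounding (measured ~1e−13, asserted ≤1e−8).

**Boundaries.** Two rules: `periodic` (circular convolution; exactly
shift-covariant) and the default `mirror`, implemented as *pad once, run
periodic, crop*: the image is symmetrically (accordion) extended by the full
analysis+synthesis support `5·(2^J − 1)` pixels, so the central crop equals
the infinite-extension computation and reconstruction stays exact. The
pyramid keeps its padded planes; replacing detail planes (as the
homomorphic filter does) updates them additively
(`padded + extend(new − old)`), so an identity edit leaves the exact
round-trip path untouched.

**Group delay.** The filters are causal, so the standalone planes are
displaced up-left: `S_J` by `(2^J − 1)/2` pixels per axis (3.5 px at J=3),
detail planes anisotropically. Reconstruction cancels this internally, but
any consumer using a plane as a spatial field must not inherit a 3.5-px
localisation bias; `WaveletPyramid.centered_coarse()` and
`.centered_details(level)` compensate by the rounded delay (≤0.5 px
residual). The quotient denominator and all texture measures use the
centred accessors.

**Feasibility.** Level `J` requires `2^J ≤ min(M, N)`; the error message
names the deepest feasible level.

## Homomorphic wavelet filter (HWF)

Pipeline: `log(f+1)` → decompose to `J` levels → multiply each detail
plane's centred 2-D Fourier spectrum by the Butterworth high-pass gain
`H(u,v) = 1/(1 + (D0/D(u,v))^{2n})` → invert the transform. Defaults
`J = 3`, `D0 = 0.95`, `n = 2`. `H = 0` at the exact spectrum centre (the
`D → 0⁺` limit), `H(D0) = 0.5`.

Two deliberately exposed ambiguities:

- **Frequency grid** (`freq_grid`). With `D` measured in raw frequency-bin
  units (`"index"`), a cutoff of 0.95 lies inside the first bin: the filter
  only suppresses the near-DC content of the detail planes and the
  "illumination estimate" is nearly the whole log image. With `D` in
  cycles/pixel (`"normalized"`, the default), 0.95 sits just beyond the
  Nyquist corner (≈0.707): the entire detail spectrum is attenuated, hardest
  at low frequencies, and `Ĩ` is genuinely smooth — the only reading under
  which the filter performs the illumination estimation it exists for, so it
  is the default; the literal index grid remains available.
- **Which levels are filtered** (`all_levels`). The default filters every
  level's detail pair (illumination leakage is distributed over all
  scales); `all_levels=False` restricts to level J only.

The classical Fourier-domain homomorphic filter with the Butterworth
transfer `h(ω) = g_l + (g_h − g_l)/(1 + (d0/‖ω‖)^{2n})` (defaults
`g_l = 0.5`, `g_h = 2.0`, `d0 = 0.95`, `n = 2`) is implemented as the
fidelity baseline; its gain is `g_l` at DC and `(g_l+g_h)/2 = 1.25` at the
cutoff. Because it *boosts* high frequencies and halves the DC in log
space, its output deviates from the input far more than the HWF's, which is
what the PSNR comparison in the acceptance surface measures.

The log transform uses a unit offset (`log(f+1)`) so zero pixels stay
finite; `exp(·) − 1` inverts it, and the same offset is used wherever a
reflectance enters a logarithm.

## Perona–Malik diffusion

Explicit 4-neighbour scheme, mirror boundaries,
`I ← I + dt·Σ g(|∇_d I|)·∇_d I`, conductance `exp(−(x/κ)²)` (or rational).
Stability requires `dt ≤ 0.25`; mirror boundaries make the scheme
flux-conserving (global mean preserved to ≤1e−6 relative) and the explicit
update obeys a discrete extremum principle. Defaults `iterations = 30`,
`κ = 30` (0–255 scale), `dt = 0.2`: enough smoothing to flatten within-object
texture and sensor noise while object boundaries (contrast ≫ κ) survive —
the numerator of the quotient should carry object structure, not speckle.
The tests assert only the qualitative properties (conservation, extremum,
edge retention vs a box blur), not these particular values.

## Wavelet-quotient image

`WQI = Diffuse(f) / max(S_J f, ε)` with `ε = 1e−6 · max(f, 1)` (relative, so
the quotient is scale-invariant) and the *centred* coarse plane. Diffusion
is applied on a canonical 0–255 scale and scaled back
(`diffuse_canonical`), because κ is an absolute intensity and raw diffusion
would break degree-zero homogeneity; with this normalisation
`WQI(a·f) = WQI(f)` exactly, tested at `a ∈ {0.5, 2, 4}`. An all-zero image
yields an all-zero quotient. The quotient recovers reflectance structure
*finer than the coarse scale*: object-bulk reflectance (an animal much
larger than `2^J` pixels) is absorbed by the denominator by construction.
The self-quotient image (Gaussian denominator) is provided as comparator.
Quotients are kept raw (no renormalisation to 0–255); the synthesis step
consumes them through `log(WQI + 1)`.

## Texture measures

On the centred level-J detail pairs, treated as per-pixel gradient vectors:
`MMD = |M_J f₁ − M_J f₂|` and
`TDR = 1 − 2·Σ_{3×3} CC / Σ_{3×3} (M₁² + M₂²)` with `CC` the signed dot
product. `TDR ∈ [0, 2]` (AM–GM), 0 for identical texture, 2 for opposed
gradients; where both neighbourhoods are textureless the denominator
vanishes and TDR is defined as 0 ("no texture, no change" — conservative
with respect to the synthesis gain). 3×3 sums use symmetric padding. A pure
global gain `g` scales both detail planes, giving the analytic background
value `TDR = 1 − 2g/(1+g²)` (0.2 at g = 2), safely below the 0.5 gate. No
thresholding of near-zero gradients is applied before the dot product.

## Synthesis and detection

`f_syn = exp(clip(α·(Ĩ_c − Ĩ_r), ±50) + log(r̃_c + 1)) − 1`, `α = c = 2`
where `TDR > γ = 0.5`, else 1. The gated-difference reading `α·(Ĩc − Ĩr)`
is the default (the ungated branch must reduce to the plain illumination
difference); the strict-literal `α·Ĩc − Ĩr` is available behind a flag.

Foreground: exact 1-D k-means (k = 3) on the synthesized intensities by
weighted dynamic programming over sorted unique values — optimal 1-D
clusters are contiguous runs, so the DP attains the global SSE optimum
deterministically, with no seed or restarts (images with >1024 unique values
are first binned to 1024 weighted representatives). The brightest cluster
is foreground. If the brightest cluster centre is less than 1.5× the
darkest (`min_contrast_ratio`), the frame has no genuine multiplicative
foreground contrast (e.g. the reference compared against itself, or a pure
lamp change with no animal) and the mask is empty; a constant image
degenerates to all-true.

Boundary: `MMD > Mth`. The default `Mth` policy (`"otsu-log"`) is a
two-stage Otsu on the `log1p` histogram: the first split separates changed
from unchanged pixels, the second — within the changed class — separates
strong object boundaries from moderate ambient change (moved straw,
globally rescaled texture after a lamp switch). MMD magnitudes are
long-tailed, hence the log domain. Plain `"otsu"` and fixed values remain
available.

Combination: close the boundary with the 3-px circular element (the 3×3
cross); `sub = fg XOR closed`; drop components below `min_area_frac = 1%`
of the image (sized to eliminate piglet-scale blobs and moved-straw
patches while never threatening a sow-scale region); `com = sub OR closed`;
drop small components again; keep the largest 8-connected component; fill
holes; finally erode by `trim_radius` (0 for the bare primitive, 2 in the
pipeline defaults) — the boundary band straddles the true edge, and
unioning its closed form grows the mask outward by about the band half-width,
which the trim removes (measured as a consistent IoU gain across scene
types). Shape features: area, centroid, and the angle between the x-axis
and the ellipse major axis in (−90°, 90°], from image moments.

## GMM baseline

Per-pixel Stauffer–Grimson mixture (K = 3, learning rate 0.01, 2.5σ match,
background ratio 0.7), vectorised over pixels; warm-up on the animal-free
reference segment. `distance()` exposes the Mahalanobis distance to the
nearest background mode as a continuous ROC score (computed before the
update, so a just-replaced component cannot mask a foreground pixel). Its
raw masks are post-processed through the same boundary/morphology path as
the primary pipeline, so the comparison isolates the modelling difference.
ROC rates are the standard `TPR = TP/(TP+FN)`, `FPR = FP/(FP+TN)`.

## Synthetic scenes

`synthgen` realises the image model generatively: straw floor = smoothed
seeded Gaussian noise (base 1.0, amplitude 0.08, correlation 2 px);
sow = ellipse (default semi-axes ≈ 31% × 15.5% of the frame, ~15% of pixels,
matching a sow filling a good part of a pen camera's view) with its own
texture (base 1.9 — a light-coated sow on darker bedding — amplitude 0.25,
≥3× the straw amplitude so foreground texture is distinctly stronger);
piglets = small blobs; illumination = level × {uniform, ramp, spot} field,
multiplied by persistent lamp-event gains; `image = clip(i·r + noise,
0, 255)`. Straw dynamics re-draws a fraction of 16-px patches per frame
with feathered blending (dragged straw has no crisp rectangular boundary).
The reference frame is the background state immediately before the animals
enter — the frame a practitioner would pick as reference. Same seed, same
bytes.

Canned study conditions (`scenes.study_scene`): `static`, `moving`
(sow walks ~1 px/frame), `lamp_step` (lights to 50%, later 3× back up, from
a lower base level so the bright phase stays in 8-bit range), `motionless`
(50 identical-pose frames), and `dirty_sow` (sow texture matched to straw —
the documented failure mode: when foreground and background texture are
statistically alike, the TDR gate and the boundary map lose their signal,
and no guarantee is made). Piglet paths keep clear of the sow: the
sow-only overlap score is only well defined while the animals are
separated; an animal pressed against another merges into one component,
which this method cannot split (a known limitation of the combination
step).

Default straw churn in these recipes is 0.5% of patches per frame (~1.3
patches every frame at 256²) — bedding rearranges near the animals over
minutes, not wholesale per frame.

## Problem sizes and performance

The shipped evaluation runs 256×256 scenes with 64 reference + 50–60 animal
frames (one frame ≈ 0.5 s on one CPU core); the baseline comparison uses
ten 160×160 twelve-frame scenes. These sizes keep full multi-scene sweeps
comfortable on a laptop while leaving the sow ≈ 160 px long — large against
the `2^3` analysis scale, as in the motivating recordings.

## Known limitations

- Dark phases (lamp gain 0.5) compress the synthesized contrast; across
  wide seed sweeps the per-frame overlap occasionally dips to ≈0.78 there,
  against ≈0.88 typical elsewhere.
- The WQI does not recover object-bulk reflectance (see above); its role in
  the pipeline is carrying fine structure, and the recovery property is
  only claimed for reflectance structure finer than the coarse scale.
- MMD is not illumination-invariant (it scales with the lamp gain); the
  two-stage threshold policy contains, but does not eliminate, its response
  to global gain changes.
- Touching animals merge into one component; the subtraction step separates
  satellites connected by thin necks only.
- The generator does not model camera gain/gamma, shadows cast by the
  animals, or photorealistic straw; conclusions from passing tests are
  about the model's behaviour under multiplicative illumination, not about
  any particular camera.
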