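# Methods

`bulbdir` estimates the 3D growth direction of a plant bulb (basal root
plate → tip) from three simultaneous x-ray projections, the way a
planting line would image bulbs passing on a conveyor. This note
documents the model, its parameters and the design decisions; nothing
here states a result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Imaging model

Three detector planes sit at equal height with horizontal normals fanned
out 60° apart (`geometry.build_detector_ring`). The world frame is
right-handed with z up; each detector is an origin plus orthonormal
in-plane axes `axis_x`, `axis_y`, with normal `axis_x × axis_y` pointing
toward the source. Projection is parallel-beam: the 2D-to-3D mapping
uses only ray *directions*, never a source position, so parallel
geometry is the minimal faithful model and cone-beam effects are out of
scope.

A radiograph is a line-integral attenuation image: air ≈ 0, bulb
bright. The simulator integrates attenuation along rays anti-parallel to
the detector normal with trilinear sampling at a step of half a voxel
(midpoint rule; the uniform-cube test bounds the quadrature error at
~1%). Rays are clipped to the sphere known to contain the bulb, which
changes nothing analytically (attenuation is zero outside) and keeps the
projector fast.

## Per-view features (105 per image)

Every histogram below is z-scored with the population standard
deviation; a degenerate-variance guard (std < 1e-12) emits all zeros.
Angular histograms have 36 bins of 10°, measured about the silhouette
centroid from the image +x axis (bin *i* covers [10°·i, 10°·(i+1))).

* **Shape (36).** Threshold at 5% of the image maximum → silhouette;
  PCA of pixel coordinates gives centroid, orientation α and semi-axis
  extents (a, b). A matched ellipse shares centroid and α, with both
  semi-axes rescaled by one common factor so the continuous ellipse area
  equals the silhouette pixel count (the same-area comparison,
  preserving aspect ratio). The signed difference silhouette − ellipse
  (+1 protrusions such as the tip, −1 concavities) is binned angularly.
  Signed binning keeps tip and notch information distinct at no extra
  dimensionality.
* **Edge (36).** A multiscale Hessian vesselness filter (σ ∈ {3, 5, 7}
  px, per-pixel maximum over scales) highlights the layered shells and
  central shaft. At each scale the image is Gaussian-smoothed, the 2×2
  Hessian formed by central finite differences, eigenvalues ordered
  |λ₁| ≤ |λ₂|, and the score is
  `exp(−λ₂²/(2λ₁²β²)) · (1 − exp(−λ₁²λ₂²/(2c²)))` gated on λ₁ < 0, with
  β = 0.5, c = 15. Note this differs from the classical 2-D Frangi
  filter in two ways (the blobness ratio is λ₂/λ₁ rather than λ₁/λ₂, and
  the gate is on λ₁ rather than λ₂); `classical=True` switches to the
  original form. The default variant consequently favours
  comparable-eigenvalue structure over clean ridge crests — the
  ridge-crest unit test therefore exercises the classical variant, while
  a brute-force convolution/finite-difference/eigenvalue oracle pins the
  default variant to 1e-9. Because c is an absolute intensity constant,
  the radiograph is rescaled to max = 255 (`intensity_scale`) before
  filtering; on unit-scale line integrals the structure term would be
  ~1e-15 and the filter identically zero. Vesselness values inside the
  silhouette are accumulated (weighted, not counted) into the angular
  histogram, preserving edge strength.
* **Texture (33).** Local binary patterns on a radius-2 circle with 6
  samples (bilinear interpolation; bit = 1 iff neighbour strictly
  exceeds the centre; bits clockwise from the +x sample, first sample
  most significant). Codes with ≤ 2 circular transitions are uniform —
  exactly 32 of the 64 six-bit codes — and get one bin each in ascending
  code order; all other codes pool into a 33rd bin. Codes are computed
  over the whole image but histogrammed only over silhouette pixels, for
  background invariance. Border pixels of width r are excluded.

All histograms are centroid-relative, so features are invariant to the
bulb's position in the frame, and the 5% threshold makes shape features
invariant to global intensity scaling.

## Angle regression

Targets are (cos θ, sin θ) pairs — the angle is periodic — and
predictions are decoded by atan2(sin-component, cos-component) after
projection to the unit circle. Three regressors share this interface:

* **Kernel SVR**: two independent ε-SVRs (ε = 0.01, C = 10), Gaussian
  kernel `exp(−‖x−x′‖²/(2w²))` with width w = 500. ε and C are not
  first-principles constants; they were fixed once by a coarse line
  search on phantom validation data and exposed in config. Note that on
  z-scored 105-dim features ‖x−x′‖² ≈ 200, so w = 500 yields a nearly
  flat kernel and close-to-linear behaviour — the observed weakness of
  SVR on this task is consistent with that. The alternative
  parameterization `exp(−‖x−x′‖²/w)` is available via
  `width_param="plain"`.
* **Kernel ELM**: the closed-form kernel ridge solution
  `(K + I/C)⁻¹ Y` with the same kernel and C = 100. The solution is
  deterministic; an optional seeded anchor subsample (`n_anchors`)
  supplies the randomized variant, and the evaluation harness can
  aggregate 20 seeded runs.
* **ANN**: a fully connected 105-60-30-15-2 network, tanh hidden
  activations, linear output. The loss is the MSE between the output
  *projected to the unit circle* and the target (plain MSE via config).
  Training is full-batch quasi-Newton (L-BFGS) with seeded
  initialization, a gradient tolerance of 1e-6 and a 1000-iteration cap
  — the same full-batch, gradient-tolerance-stopped regime as scaled
  conjugate gradient, for which the ecosystem here has no robust
  implementation. Fixed seed ⇒ bit-reproducible training.

No feature standardization is applied beyond the per-histogram z-scores
already inside the feature vector.

## 2D → 3D mapping and filtering

A predicted in-plane angle θᵢ defines the unit vector
vθ = cos θᵢ·axis_x + sin θᵢ·axis_y; the true 3D direction must lie in
the *solution plane* spanned by vθ and the detector normal nᵢ, i.e. be
orthogonal to n_S(i) = vθ × nᵢ. For a view pair the direction is the
intersection line n_S(i) × n_S(j), normalized. The cross product fixes
only a line; the sign is disambiguated by requiring the projection of
the candidate onto detector i to point *along* θᵢ — the 2D angle is a
full-circle direction (both sine and cosine are regressed), so this
information exists.

Directions store a unit vector plus elevation (latitude above the world
xy-plane) and azimuth; under this convention the spherical law of
cosines
`d = arccos[sin θ₁ sin θ₂ + cos θ₁ cos θ₂ cos(φ₁ − φ₂)]`
is *exactly* the great-circle distance, verified against arccos of the
vector dot product to 1e-9. Angles are recovered with quadrant-aware
atan2, never a bare arctan; arccos arguments are clamped to [−1, 1];
2D angles wrap to (−π, π] on construction.

The three pairwise estimates (views 1-2, 1-3, 2-3) are averaged after
hemisphere alignment (estimates 2 and 3 are flipped if they oppose
estimate 1) and accepted iff the mean pairwise great-circle distance
d̄ < τ, default τ = 40°. For d̄ < 40° the aligned-mean differs from a
proper Fréchet mean by well under a degree, which is why the cheaper
form is used. A rejected bulb is re-imaged — re-posed uniformly in
simulation — up to 3 passes; if all passes reject, the last pass's mean
is still emitted flagged low-confidence, so both the "estimate
produced" and "no confident estimate" populations can be counted.
Success for a case means an *accepted* estimate within 30° of the true
direction (the industry planting criterion); both thresholds are
configurable.

## Synthetic bulb phantoms

No imaging data accompanies the task, so phantoms emulate a tulip-type
bulb in a 3D attenuation volume: prolate ellipsoidal body (~30×44 mm),
sinusoidal concentric shells (3-7 per bulb, contrast 0.4-1.2 of the base
attenuation 0.02 mm⁻¹), a 2.5-3.5 mm-radius central shaft (2× base),
a dense basal disc (2.5×, 3 mm thick) at the root pole, a protruding tip
cone (5-7 mm) at the opposite pole, mild smoothed multiplicative noise
(5%), and per-bulb confounders: a quadratically bent shaft (35% of
bulbs, lateral tip offset 2-6 mm), and an attached lateral bulblet (20%
of bulbs). Attenuation magnitudes are chosen so the 5% threshold and the
vesselness filter behave sensibly on the projections; they are the
package's convention, not measured tissue values. Poses are uniform on
SO(3) via uniformly random quaternions. Everything is deterministic
given the seed.

What the phantoms deliberately do **not** model: x-ray spectra, scatter,
beam hardening, detector noise and blur, the conveyor belt in the field
of view, and the full biological variability of real bulbs. Passing
tests therefore demonstrate that the *algorithmic chain* works when the
assumed structures (tip, shells, shaft, basal plate) are present at
reasonable contrast — they do not certify performance on real
radiographs.

## Problem sizes and numerical choices

The library default resolution is a 128³ volume at 0.5 mm voxels with a
160×160 detector at 0.6 mm pixels. The evaluation harness and the
acceptance script run a coarser profile — 96³ at 0.667 mm, 128×128 at
0.7 mm — chosen as the smallest grid at which shells (≥ 3 px spacing)
remain resolvable by the σ = 3 filter scale; the benchmark in the test
suite uses 20 bulbs × 50 poses (3000 radiographs) and the acceptance
script 12 × 30, as its quantities are medians and rates that stabilize
well below that. Ray quadrature step is 0.5 voxel with trilinear
interpolation. The leave-one-bulb-out protocol holds out *all* poses of
a bulb together, preventing pose-level leakage.

## Known limitations

* The as-printed vesselness variant suppresses ideal ridges (see above);
  it is retained as the default for fidelity, with the classical form a
  flag away.
* Views whose normal is nearly parallel to the growth direction carry
  almost no in-plane information; such poses produce the largest 2D
  errors and are exactly what the agreement filter is designed to catch.
* The wide default kernel (w = 500) makes SVR nearly linear on these
  features; it is kept as the documented default rather than re-tuned,
  since the regressor comparison is part of what the package
  demonstrates.
* Low-contrast shells and bent shafts measurably degrade the 2D
  regression (they thin out the edge histogram's signal); they are
  included in the generator's jitter ranges on purpose.
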