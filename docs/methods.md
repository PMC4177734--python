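# Methods

This note documents the models behind `octguide`, the parameter choices
that matter, and what the simulation does and does not establish. All
lengths are micrometres; depth `z` increases downward with zero at the
undisturbed bone-surface plane.

## Phantom geometry

The phantom is two analytic height maps sampled on a 10 µm lateral grid:
the air–bone surface `z_b(x, y)` (a plane, optionally tilted, optionally
with smooth seeded roughness) and the endosteum outer boundary
`z_e(x, y)`. The cochlear shell is convex towards the outside, so `z_e`
is a spherical cap whose apex — the shallowest point — sits under the
channel centre (default apex depth 1200 µm, curvature radius 1500 µm;
an infinite radius yields a parallel plane). Beneath the boundary lies
the endosteal membrane of thickness `t_e` (default 40 µm, constrained
below 50 µm) and then perilymph. Construction validates `z_e > z_b`
everywhere; after ablation the surface may legitimately reach `z_e`
(the phantom is then flagged as a critical-structure hit, and the
surface is clipped at the perilymph interface `z_e + t_e`).

## OCT rendering

Single-scattering image formation, per A-scan:

1. piecewise-constant backscatter and attenuation per tissue class
   (air 0/0; bone 0.5 a.u., µ = ln(100)/1000 µm⁻¹; endosteum 0.9 a.u.,
   µ = 3×10⁻³; perilymph 0.02 a.u., µ = 2×10⁻⁴);
2. round-trip Beer–Lambert attenuation `exp(−2τ(z))` with the optical
   depth accumulated at voxel centres;
3. unit-mean multiplicative speckle per voxel (Gamma with shape 1/c²,
   i.e. fully developed speckle at the default contrast c = 1), applied
   before PSF blur;
4. a strong specular reflex at the air–bone interface, deposited with
   sub-voxel linear weighting so its blurred peak is centred on the true
   surface (amplitude 3, clipped by the dynamic range — emulating the
   saturated surface reflex of the real scanner);
5. anisotropic Gaussian PSF, 18 µm axial / 35 µm lateral FWHM;
6. additive exponential noise with mean equal to the noise floor
   (default 0.005 of the unit dynamic range), then clipping to
   [0, dynamic range].

The bone attenuation default is chosen so that the round-trip bone signal
decays to the noise floor at 500 µm depth, matching the ~0.5 mm imaging
depth of swept-source OCT in compact bone; this single choice fixes the
foresight geometry of the whole problem (the boundary becomes visible
roughly five 100 µm ablation rounds before exposure). Refractive indices
default to 1.0 (geometric depth = optical depth); per-tissue indices are
configurable and shift the apparent depth of subsurface interfaces, but
the loop is self-consistent for any constant choice because planning,
termination and evaluation all live in the same apparent-depth frame.
Default sampling is 20 µm lateral and 6 µm axial (the axial pitch is
validated against Nyquist for the 18 µm PSF).

What the renderer does **not** model: multiple scattering, polarisation,
interferometric signal formation and speckle correlation between rounds
(speckle is redrawn independently per acquisition, which makes temporal
compounding maximally effective — real decorrelation after ablation and
water spray is partial), sensitivity roll-off, carbonisation, and fluid
in the crater. Passing tests therefore demonstrate the *control* logic
under a faithful signal/noise geometry, not photorealistic OCT.

## Ablation model

A pulse of duration τ ∈ [20, 100] µs removes a Gaussian crater
`d(r) = d₀ exp(−2r²/w₀²)` with `w₀ = 100 µm` (1/e² radius equal to the
spot radius of the 200 µm TEM₀₀ beam) and `d₀ = τ × 1 µm/µs`, the linear
interpolation of the printed endpoint pairs (20 µs → 20 µm,
100 µs → 100 µm). Energy is linear likewise, 4.2–28.5 mJ. Craters add;
thermal diffusion, debris and water-spray dynamics are out of scope.

## Enhancement chain

**History compounding.** The library operation `history_compound` is a
masked temporal mean: prior volumes co-registered to the current pose are
averaged per voxel wherever their lateral change mask is clear. Inside
the channel, however, essentially every column is re-ablated every round,
so a purely mask-based scheme would retain no usable history exactly
where the boundary must be detected. The loop therefore uses
`rescaled_history_compound`: ablation deepens a column by a known amount
Δd while the subsurface anatomy stays put, so a history column multiplied
by the round-trip factor `exp(2 µ_bone Δd)` aligns its subsurface signal
with the current round. Since that rescaling amplifies the history's
detector noise equally, rounds are blended with inverse-variance weights
`exp(−4 µ_bone Δd)` — recent, lightly-ablated history dominates and old
deep history fades out. Δd comes from the per-round detected surface
maps; µ_bone is a config parameter defaulting to the renderer's bone
attenuation (in reality: a literature value for compact bone).

**Attenuation compensation.** Energy-remaining normalisation with
contrast exponent n (default 2):
`out(w) = I(w)ⁿ / (2 Σ_{w'>w} I(w')ⁿ + floor)`. Three guards make it
noise-robust: the mean noise floor estimated from the deepest decile is
subtracted first; the tail integral extends only over the next 500 µm
(beyond light penetration only residual noise energy would accumulate in
the denominator); and the deepest 8 samples, where no tail remains, are
zeroed. The output is rescaled to the input dynamic range.

## Surface extraction

First suprathreshold crossing per A-scan (default threshold 0.5 of the
dynamic range), climbed to the local specular peak and refined to
sub-voxel by parabolic interpolation; grey morphological closing then
opening (3×3) removes outlier spikes. Two robustness details: isolated
A-scans without a crossing can be inpainted by the morphological result
(`fill_invalid`), and a crossing whose peak is weaker than 0.8× the
column maximum is re-seeded at the dominant specular — at a steep relief
step (channel wall, deep pit) the lateral PSF leaks the shallow side's
reflex into the neighbouring column and the first crossing would
otherwise report the wrong surface.

## Boundary segmentation

Per B-scan frame, on the attenuation-compensated compound: Gaussian
smoothing (σ = 1.5 voxels axial, 2 voxels lateral within the frame), the
axial gradient, and per A-scan the largest positive gradient in a window
from 80 to 600 µm below the detected surface (the rise into the brighter
endosteum). A candidate must be a strict local maximum inside the window
— an argmax pinned to a window edge is censoring, not an edge. Candidates
of adjacent A-scans within 2 axial voxels are linked; chains shorter than
10 A-scans are dropped. Because the in-frame smoothing correlates
neighbouring A-scans, speckle can still form linked chains; a robust
global consistency filter removes them: the anatomical boundary is a
near-spherical shell, so an iteratively reweighted quadratic surface is
fitted to all linked points and only points within a band of
max(25, min(3.5·MAD, 60)) µm survive. Confidence is the fraction of
channel A-scans with a surviving linked candidate.

The compensated volume is where the faint boundary is *detectable*, but
its depth-monotone gain skews the gradient peak tens of micrometres deep;
each candidate is therefore re-localised on the pre-compensation compound
within ±5 voxels (two-pass detection/localisation).

The bicubic fit (`LSQBivariateSpline`, interior knots every 150 µm,
5 Tukey-reweighting iterations cut at 3× the median absolute residual)
is gated at confidence ≥ 0.5 and is trusted only on the lateral support
mask — linked candidates dilated by one knot interval; outside it the
spline is pure extrapolation. In the loop the fitted stop surface is
additionally clamped to ±60 µm (the consistency cap) around the robust
quadratic, bounding what a sparsely supported spline cell can do.

## Planning and termination

Greedy coverage: repeatedly take the unclaimed in-mask position of
maximal residual thickness strictly above target + margin (ties broken
lexicographically by (y, x)), plant a pulse, claim a disc of the minimum
spacing (150 µm = 0.75 spot diameters; Gaussian crater tails make
sub-diameter spacing useful). Duration: clamp the excess to [20, 100] µs
under the 1 µm/µs map, then quantise to short 20 / middle 60 / long
100 µs at excess thresholds 100 and 300 µm (a continuous mode exists
behind a flag). The planner's margin equals the termination tolerance
(default 10 µm ≈ half the axial resolution), which yields the progress
guarantee: not terminated ⇒ at least one pulse, at the global maximum.
Termination requires thickness ≤ tolerance at every position of the
*channel bottom*.

## The closed loop

Per round: optional rigid jitter (test harness) → render → landmark
tracking (when enabled) and resampling of the acquisition into the
reference frame → surface detection on the current volume →
attenuation-rescaled compounding → compensation → segmentation → stop
surface → thickness map → termination check → greedy plan → displacement
correction → ablation. Three stateful safeguards matter:

* **Stop-surface memory.** The anatomy is static, so wherever a round has
  a trusted fit the stop estimate is stored, and positions that later
  lose visibility (late in a run the boundary sits barely beyond the
  80 µm window offset, and linking gets sparse) keep their last good
  estimate instead of reverting to the blind fallback — firing
  virtual-infinity pulses into a 100 µm residual layer would destroy the
  endosteum.
* **Fallback virtual structure.** Positions never yet seen plan against a
  surface parallel to the round-0 bone surface at a nominally infinite
  depth; durations clamp at 100 µs, which is exactly the per-round depth
  cap, and termination cannot trigger while any bottom position is still
  unseen.
* **Dead-reckoning budget.** The cumulative commanded crater depth per
  position bounds the effective channel bottom from below
  (`bottom = max(detected, original + commanded)`). At steep relief the
  optical surface reading saturates on the shallow side of the step; the
  commanded budget cannot be fooled that way, so the planner stops
  re-firing into walls and pits it cannot see properly.

Termination and evaluation use the **bottom mask**: the channel disc
shrunk by one spot radius (100 µm). A 200 µm Gaussian spot cannot cut a
vertical wall, so the outer annulus is sloped wall rather than channel
bottom; planning still covers the full 1 mm disc. Evaluation compares the
*ground-truth* bottom (not the detected one) with the loop's own stop
surface — the strictest reading — and reports mean absolute error,
standard deviation, maximal penetration and the hit flag.

All randomness (render speckle and noise, jitter) derives from the single
config seed; identical configs reproduce bit-identical runs.

## Calibration

The calibration pattern is the (n_cells+1)² lattice of square corners on
n_planes equidistant axial planes (defaults 8×8 corners × 5 planes over a
4×4×2 mm working space → 320 pairs); the evaluation pattern is the cell
centres (the 45°-rotated squares) on the axial midplanes, the points
farthermost from calibration support. Detection of ablated points is
simulated as a smooth low-order harmonic distortion field (≤ 50 µm
amplitude, seeded phases) plus isotropic Gaussian noise (σ = 10 µm,
between the 2–3 µm optics accuracy and the OCT resolutions). The mapping
is a least-squares tricubic B-spline; the default knot lattice gives each
axis as many intervals as its resolvable sample clusters minus three,
the densest lattice a gridded pattern keeps full-rank (a one-interval-
per-cell lattice would have more coefficients than samples per axis).
Explicit `knot_intervals` and a ridge term are available for scattered
coverage. Errors are Euclidean `|laser − f(imaging)|` with per-role
breakdowns.

## Tracking

Four landmarks on an 800 µm ring (equally spaced; centroid at the channel
centre so rotational estimation error is not amplified there), each
ablated with two stacked 100 µs pulses. Localisation: depth-weighted
centroid of the crater relief (height minus window median, clipped at
zero) in a 3-spot-diameter window, with the channel disc masked out once
the cochleostomy exists; the axial coordinate is the local baseline
level. Displacement: closed-form SVD rigid registration of detected
versus reference positions (reference measured right after landmark
ablation); fewer than three valid, non-collinear correspondences raise a
tracking-lost error that halts the loop. Corrections map every planned
pulse position through the estimated transform; pulses leaving the
working space are dropped and logged.

## Known limitations

* Speckle redraw per round makes compounding an upper bound on what real
  (partially correlated) speckle allows.
* The crater model is deterministic and exactly known to the controller;
  the dead-reckoning budget is correspondingly exact, whereas a real
  system would carry pulse-to-pulse depth variance and calibration drift.
* The channel wall region is excluded from the accuracy metric by
  construction (see bottom mask); wall shape is not controlled.
* Rigid motion only; no deformation, no water film, no tissue
  dehydration.
* The segmentation trusts a globally smooth boundary; pathologies with
  step-like anatomy would defeat the consistency filter and would need a
  different linking model.
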