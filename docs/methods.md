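# Methods

`vesselflow` infers the direction of blood flow in a single vessel
segment from a few seconds of colour video plus a hand-drawn binary
segmentation of that vessel.  The physical signal it exploits is the
plethysmographic pulse wave: each cardiac ejection transiently raises
the blood volume under every patch of the vessel, and because
oxyhemoglobin absorbs most strongly in green light, the patch's
green-channel intensity dips by a fraction of a percent.  The dip is far
below visual threshold, but it *propagates* along the vessel at the
pulse-wave speed, so the signal at a downstream point is a delayed copy
of the signal upstream.  Direction inference reduces to estimating the
sign of that delay.

## Pipeline

1. **Stabilization** (`stabilize`).  Every frame is registered to a
   reference frame (the one the segmentation was drawn on) with a
   6-parameter affine model, estimated by coarse-to-fine gradient-based
   Gauss–Newton (3 pyramid levels, ≤ 50 iterations per level,
   convergence when the parameter update falls below 1e-4).  Two
   robustness measures matter in practice:

   * estimation runs on a *pulse-band-suppressed* grey stack: the
     0.8–3 Hz temporal component is subtracted from the frames used for
     estimation (only).  The pulse is a photometric change, not motion;
     left in, a least-squares fit partially explains the rhythmic
     darkening of the vessel as sub-pixel warping, which is exactly the
     artefact stabilization must not inject.  The corollary limitation:
     genuine camera motion *inside* 0.8–3 Hz is invisible to the
     estimator by construction.
   * residuals are Huber-weighted (IRLS), so localized intensity
     outliers do not steer the global fit.

   Transforms that displace no pixel by more than 0.02 px are snapped
   to the identity, so a motion-free clip passes through without
   resampling.  Frames whose registration residual would *grow* are
   passed through unwarped with a warning.  An optional second stage
   removes slow (< 0.5 Hz by default) whole-frame translational drift by
   low-pass filtering the estimated translation trajectory and warping
   it out; it is a simple temporal suppressor for breathing-like drift,
   not a phase-based motion-attenuation pipeline, and it leaves in-band
   colour oscillations untouched.

2. **Eulerian colour magnification** (`enhance`).  With I_t a frame and
   I&#773; the per-pixel temporal mean, the band-passed deviation
   δ_t = bandpass(I_t − I&#773;) is amplified:
   I′_t = I_t + α·δ_t.  The band-pass is an ideal (brick-wall)
   frequency-domain filter over 0.8–3 Hz — wide enough to catch
   intraoperative heart rates outside the normal 60–100 bpm
   (1–1.67 Hz) range — so any in-band sinusoid is magnified exactly
   (1+α)-fold and out-of-band content is untouched.  δ may be blurred
   spatially (Gaussian, σ = 3 px default) before amplification as a
   cheap stand-in for a full spatial pyramid decomposition; direction
   inference depends on vertex-mean signals, not on the visual quality
   of the reconstruction.  Display frames are clipped to [0, 1], but the
   un-clipped amplified green channel is retained for analysis so
   clipping can never distort the signal.  α defaults to 50 and is
   configurable; since amplification is a positive real gain at every
   frequency, the *phase* analysed downstream is identical with or
   without enhancement — the stage exists for signal-to-noise and for
   visual inspection.

3. **Centerline extraction** (`centerline`).  The mask is thinned to a
   1-px structural skeleton (scikit-image), spur branches shorter than
   10 px — thinning artefacts of hand-drawn polygons — are pruned, and
   the skeleton is traced into an ordered pixel path.  The tracer is a
   two-pass greedy walk: from the first scanned pixel (column-major
   scan) it walks to one free end, then restarts from that end and
   walks the whole path, which guarantees complete traversal of a
   simple path regardless of scan start.  Neighbour preference is
   4-connected first, then diagonal (each clockwise from north): a pure
   clockwise order over all 8 neighbours would cut right-angle corners
   by stepping diagonally past the corner pixel.  Junctions are
   detected with the Rutovitz crossing number (≥ 3) and traversed
   deterministically with a warning.  The path is downsampled by
   k = 25 (keep every k-th pixel plus both endpoints, vertex count
   ⌈(L−1)/k⌉+1); an optional auto mode picks the largest k ≤ 25 that
   keeps at least 5 vertices.  Vertex spacing is reported in pixels;
   conversion to millimetres requires user-supplied pixel size.

4. **Per-vertex signals and phase** (`signals`).  Every mask pixel is
   assigned to its nearest polyline vertex (Euclidean, ties to the
   lower index); each vertex's time series is the mean amplified green
   intensity of its cell.  The heart rate f_heart is the in-band DFT
   bin of largest magnitude of the vertex-averaged series (rectangular
   window, no zero-padding, so the estimate snaps to the grid fps/T —
   0.1 Hz for a 10 s clip).  The phase θ ∈ [−π, π] of every second
   vertex (stride 2, configurable) is the argument of its DFT
   coefficient at the heart-rate bin.  Under the forward-DFT sign
   convention a signal delayed by Δt has its phase changed by
   −2π·f·Δt, so θ decreases downstream; a property test pins this sign.

5. **Direction inference** (`direction`).  For consecutive sampled
   vertices, Δθ = θ_{i+1} − θ_i is taken as the raw difference of two
   principal-value angles (range (−2π, 2π), deliberately *not*
   re-wrapped).  A pair is accepted only inside the reliability window

       2π·f_heart / f_video ≤ |Δθ| ≤ π.

   Below the lower bound the implied delay is under one frame interval
   (likely noise); above π the difference is consistent with phase
   wrapping across ±π and is rejected rather than "corrected" —
   re-wrapping would silently convert wrapped pairs into plausible
   accepted ones.  Each accepted pair votes from its higher-θ to its
   lower-θ vertex; the overall call is the unweighted majority, and an
   empty or tied vote returns an explicit *indeterminate* outcome (a
   first-class result with its own CLI exit code, not an error).

6. **Annotation** (`annotate`).  One arrow per accepted pair is drawn
   on a representative frame (the stabilization reference), tail at the
   higher-phase vertex; rejected pairs leave gaps.  A phase map colours
   every vessel pixel by the θ of its nearest sampled vertex on a
   perceptually ordered colourmap fixed to [−π, π] so colours are
   comparable across videos.  Rendering is a pure function of its
   inputs.

## Synthetic phantom (`synth`)

All testing runs against a software counterpart of a pump-driven
silicone vessel phantom: a straight or S-curved tube (radius ≥ 2 px) in
a tissue-coloured scene.  The pump drive is a rectangular cycle —
period 1 s, on for 1/3 s, off for 2/3 s, approximating systolic and
diastolic time fractions — optionally Gaussian-smoothed (σ = 0.05 s
default) so the fundamental dominates the band; σ = 0 reproduces the
hard on/off cycle.  The green channel at arclength s and time t is
baseline − amplitude · drive(t − s/v) for wave speed v (the pulse
*decreases* green, as blood-volume absorption does; inference is
sign-agnostic since it uses relative phase only).  The red channel is
elevated (dyed-red contrast), a static smooth texture (amplitude 0.04)
makes the scene realistically non-featureless — a flat background would
render registration ill-posed — and per-pixel Gaussian noise
(σ = 0.005 default, pulse amplitude 0.05) plus optional slow global
translational jitter complete the model.  Everything derives from one
seed and regenerates bit-identically; ground truth (direction, wave
speed, per-px delay) is returned as metadata.

What the phantom does **not** emulate: specular highlights, instrument
motion, non-rigid tissue deformation, lossy-codec artefacts, vessel
branching, and depth-dependent blur.  Passing tests therefore
demonstrate the correctness of the signal chain and its closed-form
properties, not clinical robustness.

## Numerical choices and edge cases

* Frames are float in [0, 1]; 8-bit I/O maps 255 → 1.0 exactly, and the
  PNG frame-stack round trip is bit-exact.  Pixel coordinates are
  (row, col), 0-based; the green channel is index 1.
* The band-pass keeps bins with f_lo ≤ f ≤ f_hi inclusive; DC is always
  removed.  Heart-rate search excludes DC and errors out if no bin
  falls in the band or the signal has no oscillation.
* Nearest-vertex ties go to the lower vertex index; vertices with no
  assigned pixels are excluded from sampling with a warning.
* Warping uses bilinear interpolation with edge replication, avoiding
  dark borders that would contaminate vertex means.
* Degenerate downsampling (k ≥ path length) keeps the two endpoints and
  warns.

## Problem sizes

Default synthetic clips are 96×160 px at 30 or 60 fps for 8–10 s
(240–600 frames); the direction-recovery sweep in the test suite runs
28 such configurations (24 inside the reliability window at both frame
rates, straight and curved geometry, both flow directions, noise up to
20% of pulse amplitude; 4 violating it), each also analysed
time-reversed and with reversed vertex order.  These sizes resolve the
1 Hz fundamental with 0.1–0.125 Hz spectral resolution and give 3–4
vertex pairs per vessel, matching the scale of the method's intended
inputs while keeping a full run of the suite around two minutes.

## Known limitations

* **Endpoint-cell bias.**  The two endpoint vertices own half-width
  pixel cells, so their effective arclength position is biased inward
  by ~k/4 px; the phase difference of a boundary pair is attenuated by
  ~1/8 relative to interior pairs (both cell width and vertex spacing
  scale with k, so the ratio is k-independent).  The sign — hence the
  direction — is unaffected; closed-form phase checks are exact only
  for interior pairs.
* **Wrap blind spot.**  True per-pair shifts with |Δθ| ∈ (π, 2π) can
  alias to an accepted difference of the opposite sign: the reliability
  window inspects only the raw difference of principal-value angles and
  cannot distinguish a shift of −(2π−x) from +x.  Shifts near 2π alias
  below the lower bound and are rejected as too small; shifts modestly
  above π may be silently reversed.  Keeping |Δθ| well below π — i.e.
  adequate frame rate for the expected pulse-wave speed — is the
  operator's lever.
* **In-band motion.**  Pulse-band suppression makes 0.8–3 Hz camera
  motion invisible to the stabilizer (see above).
* **Thinning asymmetry.**  Morphological thinning is not exactly
  mirror-equivariant; a flipped mask yields a centerline within ~1–2 px
  of the mirrored one, not identical.
* **Single vessel, no branching.**  Branched skeletons are traversed
  deterministically but only one path is analysed; segmenting one
  vessel segment at a time is the supported workflow.
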