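# Methods

This note documents the models, parameter choices and numerical decisions
behind each module, what the synthetic phantom does and does not emulate,
and the known limitations.

## Coordinate conventions and calibration

All modules share one pixel convention: 0-based `(x, y)` with `x`
rightward, `y` downward, origin at the center of the top-left pixel. The
default widefield calibration is 0.0833 mm/px in both axes, derived from an
8 cm field of view across 960 px (the multimodal-imaging resolution; the
full sensor is 1920×1200 and is block-mean downsampled by 2). The
microscope pixel pitch defaults to 790 µm / 720 px ≈ 1.10 µm/px.

The probe's circular field of view is modeled as the largest centered
circle that fits the 720×540 frame with margin (radius 264 px). The
physical probe circle is wider than the frame height and is cropped by the
sensor; keeping the modeled circle inside the frame makes coverage,
feathering and point-process areas well defined, at the cost of a slightly
smaller effective field (~0.26 mm²).

## Camera–projector homography

Projection is modeled as a planar homography (3×3, h33 = 1) between camera
and projector planes, estimated by DLT with Hartley coordinate
pre-normalization; `exact4` solves the interpolating transform from
exactly four correspondences. Degeneracy (collinear or duplicate points)
is detected from the second-smallest singular value of the design matrix.
Guidance masks are warped by inverse-mapped nearest-neighbor sampling:
binary output, no gray halos, out-of-source pixels zero. Lens distortion
and tissue topography are not modeled — the software contract is the
planar mapping.

## Risk map

The risk score is the raw per-pixel ratio `R / (G + ε)` with ε = 1
intensity unit guarding zero green, divided by the mean (configurable to
median) of the ratio over the clinician-outlined mucosa. Consequences:
the map is invariant to global illumination scale, its mucosa average is
exactly 1, and values are unitless multiples of "average mucosa". The
outline polygon is rasterized with the even-odd rule at pixel centers with
boundary pixels included; camera white balance is assumed already applied.
Heatmaps default to a 2nd–98th percentile display range for robust
contrast.

## Probe tracking

Segmentation is wrap-aware HSV gating (default teal, hue 160–200°,
S ≥ 0.35, V ≥ 0.20) followed by one 3×3 morphological opening. The tip is
the centroid of the largest 8-connected component with area inside
[20, 5000] px²; area ties break toward smaller centroid y, then x. No
tip-offset correction is applied — the ligature centroid is the tip.
Dropouts up to `max_gap` frames are bridged linearly between valid flanks
(marked `interpolated`); positions are then smoothed by a centered running
median of 5 frames (robust to single-frame misdetections; edges shrink the
window). The output for frame *t* depends only on frames up to
*t* + (window−1)/2 + max_gap, so the procedure is streaming-capable with
bounded latency. A Kalman filter was deliberately avoided: no motion model
is assumed.

## Microscopy QC and scoring

QC step 1 (contact): fraction of field-of-view pixels at or above an
intensity floor (default 10 of 255) must reach 0.5. Step 2 (content):
mean squared gradient magnitude inside the field of view must reach 5.0 —
far below any in-focus nuclei frame (~40+ on synthetic data) and far above
a defocused one (< 1 at σ = 8 px blur), so the gate discriminates focus,
not content density.

Nuclei segmentation: white top-hat background subtraction with a disk of
radius 2× the expected nucleus radius (decomposed footprint for speed),
global Otsu threshold over field-of-view pixels, watershed split on the
Euclidean distance transform seeded at local maxima, and an area filter
[12, 2000] px². Otsu on a frame with no nuclei merely bisects the noise,
so the threshold must additionally clear the sub-threshold background mean
by 3 standard deviations or the frame yields an empty set.

The baseline scorer combines three geometric features — nuclear density
(nuclei/mm²), mean nuclear area (µm²) and crowding (inverse mean
nearest-neighbor distance, µm⁻¹) — each standardized by configurable
reference center/scale and summed (unit weights, zero intercept) through a
logistic link. Reference centers (280 /mm², 55 µm², 0.033 µm⁻¹) sit
between typical normal and dysplastic values so the logistic midpoint
separates regimes. Because features are geometric, the score is invariant
to global intensity scaling. Any other scorer can be plugged in; the only
contract is determinism and output in [0, 1]. The original system used a
trained multitask network here — this package deliberately ships a
transparent baseline instead and treats the scorer as an interface.

## Fusion and guidance

Micro frames are associated to the nearest-in-time widefield frame
(tolerance 0.1 s ≈ two widefield periods; ties to the earlier frame).
Each scored frame deposits its score on every pixel within a disc of
radius 5 px (~the probe field-of-view radius at the widefield scale;
radius 0 reproduces literal per-pixel deposition) around the tracked tip.
The per-pixel mean is sum/count on demand. The guidance mask is the
conjunction: mucosa ∧ visited ∧ RG ≥ τ_rg ∧ mean score ≥ τ_mtn. Unvisited
tissue is never recommended. `update_thresholds` operates only on the two
cached fields and is bitwise-identical to recomputation, which is what
makes interactive threshold changes cheap. No default thresholds are
shipped; the CLI emits a mask-area-versus-thresholds sweep table when none
are given.

## Mosaicking and score profile

Pairwise registration is translation-only phase correlation: pixels
outside the field-of-view circle are replaced by the in-field mean, the
normalized cross-power peak is refined per axis by a parabolic fit, and
the normalized peak height is reported as confidence. Translation
dominates at 90 fps overlap; rotation and deformation are out of scope.
Offsets are chained; a link with peak below 0.2 marks the frame (and chain)
invalid and holds the last trusted offset rather than discarding frames.
Compositing is feathered averaging weighted by distance to the
field-of-view edge. The score profile accumulates arc length along the
smoothed track, assigns each scored frame the arc length of its associated
widefield frame, and averages in 0.5 mm bins (left-edge reported).

## Synthetic phantom

The generator emulates one acquisition session with a single elliptical
lesion (default semi-axes 110×70 px ≈ 9×6 mm): AF red gain 2.0 and green
loss 0.6 inside the lesion with a ~2 px feathered boundary; additive
Gaussian noise at 2 % of the 8-bit range in all modalities; a teal marker
disc (radius 8 px) moving at 8 mm/s along a waypoint polyline crossing the
lesion; widefield at 20 fps and microscopy at 90 fps on one clock for 5 s.
Microscopy frames draw nucleus centers from a hard-core (dart-throwing)
point process — normal: 150 nuclei/mm², minimum separation one nucleus
diameter, radius 4.0 ± 0.5 µm; dysplastic: 3× density, half-diameter
separation, radius 6.0 ± 0.75 µm — rendered as Gaussian blobs
(σ = 0.6 r) over a dark background. The regime of each frame is decided by
ground-truth lesion membership of the interpolated tip position; a
config-optional linear density ramp emulates a transition zone (off by
default). Everything is seeded (per-component seed sequences) and
bit-reproducible; frames are stored as 8-bit, matching real acquisition.

What the phantom does **not** emulate — and therefore what passing tests
do not demonstrate about clinical data: fiber-bundle honeycomb artifacts,
optical PSF and vignetting profiles, specular reflections and blood,
probe occlusions and marker color confounds, tissue deformation, staining
heterogeneity, and inflammation-driven false positives in the RG ratio.
Results on the phantom validate the pipeline's plumbing and algebra, not
clinical performance. In particular, phantom microscopy frames are
independent draws of the point process rather than views of one continuous
tissue, so inter-frame registration on phantom streams correctly reports
low confidence and breaks the mosaic chain; mosaicking is validated on
constructed overlapping frames of a common scene.

## Problem sizes

The default session (5 s: 100 widefield + 450 microscopy frames) is the
unit of end-to-end evaluation; the regime-separation check uses 100 frames
per regime; homography acceptance averages 20 noise realizations of a 5×5
fiducial grid with 100 held-out points. These sizes were chosen so every
evaluation is reproducible in minutes on a single core while keeping
statistical margins wide (the measured tracking error is two orders of
magnitude below the 1.5 mm bound).

## Known limitations

* The scorer baseline is morphometry, not a learned classifier; absolute
  score values are not calibrated probabilities of dysplasia.
* Chain-breaking in mosaics preserves data but collapses geometry onto the
  last valid offset; no loop closure or global bundle adjustment.
* The association model assumes a shared clock between streams.
* QC thresholds are tuned on the synthetic generator's intensity scale and
  must be re-calibrated for a real instrument.
* Pipeline stage hashing uses file names and sizes for frame directories;
  pathological same-size edits to frames without touching timestamps would
  be missed (full hashes are used for all single-file inputs).
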