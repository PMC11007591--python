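# Methods

`crowgaze` infers where a head-tracked bird is looking by combining a
species visual-field model (measured once, on restrained birds, with an
ophthalmoscopic perimeter) with a rigid-body head pose estimated from
motion-capture markers.  This note records the models, conventions and
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Coordinate conventions

The head-centric frame has its origin at the midpoint of the two eyes,
`x` toward the centre of the right eye, `y` forward and `z` up.  Directions
are (azimuth, elevation) in degrees: azimuth in (−180, 180], measured from
`+y` toward `+x` (positive toward the right eye — the source data do not fix
a sign, so this is a package convention used everywhere); elevation in
[−90, 90].  At the poles (|elevation| = 90) azimuth is undefined
mathematically and fixed to 0 so serialization is deterministic.  All public
APIs use degrees; radians appear only inside computations.

Perimeter coordinates describe the measurement arm: arm elevation `phi` in
(−90, 270] sweeps the median sagittal plane (0 front horizontal, 90
overhead, 180 rear), arm azimuth in [0, 90] runs along the arm from the
median plane to the lateral pole.  The signed arm azimuth `s` (positive
toward the right pole) makes `(phi, s)` an exact spherical coordinate system
about the `+x` axis.  Two consequences are used heavily:

* the solid-angle element is `cos(s) ds dphi`, so region areas reduce to
  one-dimensional integrals of `sin` of the boundary curves over `phi`;
* a pitch of the head about the inter-eye axis is a pure shift of `phi`, so
  the head calibration (aligning the eye–beak-tip line to elevation −10°,
  the natural perching posture) is applied exactly, without resampling.

An open representational question is whether an "unfolded 2-D" field map
equates arm coordinates with azimuth/elevation or converts exactly; the
package stores boundaries in arm coordinates (what the perimeter actually
graduates) and converts exactly wherever a head-centric direction is needed.

## Visual-field model

Each eye's monocular field is a boundary curve: at every arm elevation the
eye sees the arc from its boundary azimuth (signed toward midline crossing)
to its own lateral pole.  Binocular width at an elevation is
`max(0, b_left + b_right)`; a negative sum is a blind wedge.  Boundary
curves are piecewise-linear and periodic in `phi`; no spline smoothing is
applied (nothing in the measurements supports it).  Missing elevations are
filled by periodic linear interpolation and flagged — the original gap
filling was manual and anatomy-guided, which cannot be codified.

**Representative boundary.**  Repeated ophthalmoscope passes see the field
edge at several azimuths because the (untracked) eye moves; the
representative score is the extremum that maximizes field extent
(`max_extent`, the default; `min_extent` and `median` are available), and
the replicate span estimates the eye-movement amplitude.

**Viewpoint correction.**  The perimeter is graduated about the head centre
but each eye's nodal point sits `d/2` lateral of it, with `d` taken as 2/3
of the inter-eye-surface distance (the convention reported for corvids).
For a boundary recorded at arm azimuth `a` (crossing-signed) the limiting
ray through the nodal point makes the angle
`a' = atan2(R sin a + d/2, R cos a)` with the median plane (`R` = 280 mm for
the 560 mm arm).  This exact planar triangle shifts every boundary slightly
*toward more midline crossing* — referenced to the eye, the field reaches
farther across — and vanishes as `d → 0` or `R → ∞`.  In the
crossing-signed convention the formula is the same for both eyes.

**Regions and areas.**  Every direction maps to exactly one of: binocular,
right/left monocular (anterior if |azimuth| ≤ 90°, else posterior), blind;
pecten wedges can be overlaid on request but are excluded from scoring
(their projections move with the eyes).  Region areas are integrals of the
boundary curves on a fine (0.02°) elevation grid; the default is true solid
angle (cos-weighted), with an unweighted equirectangular "map" mode kept as
an option because published area-based scores do not state their weighting.
The four region classes plus binocular tile the sphere; the implementation
guarantees their areas sum to 4π identically, and a Monte-Carlo
classification test cross-checks the integrals.

**Chance levels.**  Under direction-uniform ("random") viewing the expected
differential looking scores are set by relative areas:
`binocular_use_chance = (A_b − A_n)/(A_b + A_n)` with `A_b` the binocular
area and `A_n` the non-binocular anterior area, and
`laterality_chance = (A_nR − A_nL)/(A_nR + A_nL)`.  Chance is always
recomputed from the supplied model rather than hard-coded, so alternative
field models stay internally consistent.  A left–right mirror-symmetric
model has laterality chance exactly 0 (the integrands are equal
term-by-term in IEEE arithmetic, so the result is an exact float zero).

**Packaged mean field.**  The published mean crow field is available only
as a figure, so `crowgaze.reference_field` packages a *synthetic
digitization*: a boundary profile on the calibrated 10° grid constrained by
every printed anchor — maximum binocular width 48.4° at elevation 16.4°,
maximum blind width 17.1° behind the head, optical axes at (62.7°, −32.9°)
right and (−59.4°, −33.8°) left, beak projection (0°, −10°), and the
area-derived binocular-use chance level −0.42 (solid angle).  The profile
between the anchors is under-determined; it was drawn once as a plausible
corvid field and its lower anterior shoulder solved (one-dimensional root
find) so the solid-angle areas reproduce the printed chance level.  A fixed
±0.3° left/right asymmetry keeps per-elevation widths unchanged while
making the model realistically non-mirror-symmetric.  The fixture is a
reconstruction, not the measured data; quantities that depend only on the
anchors (widths, chance levels) are faithful, the detailed curve shape is
not.

## Head calibration

3-D key points (eye centres, beak tip, scale-triangle corners, markers) are
reconstructed from ≥2 annotated views with known intrinsics: eight-point
essential matrix for an initial pair, cheirality-tested decomposition,
DLT triangulation, registration of further views by two-view geometry with
the translation magnitude fixed by the shared reconstruction, then a short
resection–intersection phase followed by a sparse joint reprojection least
squares (first camera fixed to pin the gauge).  Because the head-with-scale
scene is shallow relative to the camera distance, the two-view problem has
the classic near-planar twofold ambiguity; every ordered view pair is
therefore tried as the initial pair and the refined solution with the
smallest reprojection error (and all points in front of all cameras) is
kept — in simulation the spurious basin is consistently ~2× worse in
residual.  The 30 mm scale triangle fixes the metric scale; the worst edge
error after scaling is reported as `scale_residual_mm`, and the overall
reprojection r.m.s. in pixels as a quality figure.  With four views and
0.5 px annotation noise the key points land well under 1 mm at head scale
(~50 mm) in simulation.

The head frame takes `x` toward the right eye and `y` toward the beak tip
orthogonalized against `x`, then pitches about `x` so the beak tip projects
to elevation −10° *exactly* (the natural-posture convention).  The pitch
angle is solved, not fixed at −10°, because the beak tip may sit slightly
off the median plane when the eyes are asymmetric; azimuth of the beak is
preserved.  Marker positions re-expressed in this frame form the rigid-body
template; the construction is invariant to rigid motions of its input.

## Pose estimation and saccade filtering

Per-frame head pose is the proper-rotation orthogonal superposition
(Kabsch) of observed markers onto the template; reflections are excluded by
the determinant correction, which matters for near-planar marker sets.
Frames with fewer than three visible, non-collinear markers are flagged
untrackable rather than raising — downstream stages treat them as gaps.
The estimator is exact (to machine precision) on noise-free input; under
isotropic marker noise its orientation error follows the first-order
covariance `σ² M⁻¹` with `M = Σ(|r|²I − r rᵀ)` over centred template
positions, which the tests verify by Monte Carlo.  Accuracy therefore
depends on the marker spread: templates confined to the top of a ~40 mm
head give ~1° orientation noise per 0.5 mm of marker noise.

Trajectory cleaning: spike frames (displacement speed > 5 m/s, a generous
bound for a perched bird's head) are invalidated; interior gaps up to
0.1 s are filled by cubic interpolation; a fourth-order zero-phase
Butterworth low-pass at 10 Hz smooths each contiguous valid run; the series
is then resampled from the native 120 Hz onto a uniform 36 Hz working grid
(`floor(n·36/120)` frames).  The original per-subject parameters were
hand-tuned by visual inspection; these defaults are exposed in
`PreprocessConfig` and recorded in outputs.

Saccades: the axial angle speed is the geodesic rotation angle between
consecutive orientations times the frame rate; frames where it exceeds
200 deg/s form candidate events.  Supra-threshold runs separated by a
single sub-threshold frame are merged (anti-chatter; the source is silent
here), and each event is extended outward to the surrounding local speed
minima so amplitudes reflect movement onset-to-offset rather than the
threshold crossings.  Events that are *both* shorter than 50 ms and smaller
than 5° are demoted to the inter-saccadic interval (the stated AND rule);
they are indistinguishable from tracking noise.  The threshold is applied
at the working rate by default (switchable); note that at 36 Hz a genuine
5° saccade completed between two samples peaks at only 180 deg/s, so
small-saccade sensitivity is materially better at the native rate.

## Gaze analysis

The target direction is `direction(Rᵀ(p_target − p_head))`, undefined where
either track is invalid or the target coincides with the head origin.
Analysis windows are 1 s from each movement onset (M1 wiggle, M2 throw,
M3 still), pooled per subject × session × movement; saccade and invalid
frames are excluded from dwell *before* pooling.  Dwell seconds per region
sum to the retained time exactly.  Heatmaps are 5°×5° azimuth × elevation
occupancy grids normalized to 1 (an equirectangular map: lateral bins near
the poles over-represent solid angle, as the marginal-histogram test makes
explicit).  The binocular use score `(B − N)/(B + N)` and laterality score
`(nR − nL)/(nR + nL)` are NaN (flagged, never zero) when their denominator
is empty.  `score_table` appends chance-adjusted columns
(`score − chance`); fitting mixed models on the table is deliberately left
to standard statistics packages.

## Synthetic data

The simulator generates the full study geometry: a 4×4×4.6 m room, perch
head position at (2, 2.2, 2.3) m, an experimenter who wiggles an object at
2 Hz for 5 s (M1), throws it on a 0.9 s ballistic arc to the ground or wall
(M2), after which it lies still (M3); the ceiling scenario wiggles only.
Between trials the object is carried back smoothly.  Head gaze is a
fixation–saccade process: per movement phase a region preference
distribution picks binocular / right / left; the target is held at a
sampled offset (≤15°, the reported scale of untracked eye movement) from
the region's reference direction — the beak projection for binocular, the
optical axis for lateral — rejection-sampled to lie inside the region.
Fixation durations are exponential (mean 1 s, floor 0.2 s — inter-saccadic
intervals of this order are typical of the recordings this emulates), and
fixations break at movement onsets (stimulus-driven re-fixation) or when a
moving target drifts beyond the jitter bound.  Transitions are minimum-jerk
rotations with a 1000 deg/s peak-speed main sequence (floored at two native
frames, so small saccades are abrupt — consistent with fast avian head
movements); binocular fixations during the throw become smooth pursuit,
rate-limited at 150 deg/s with catch-up saccades aimed at the target's
predicted landing-of-saccade position.  Markers are rendered from the true
poses with isotropic Gaussian noise and independent per-sample dropout.

Ground truth stores the true poses, every inserted saccade, and per-frame
region labels *re-derived* from the generated poses and the model, so the
truth is self-consistent by construction.  Synthetic perimetry samples the
true boundary curves on the 10° (or 30°) grid, retracts each replicate by a
uniform eye-movement draw, adds reading noise, and quantizes to the 1°
arm graduation (quantization can be disabled for exact round-trip tests).
A signed eye-rotation offset emulates induced convergence/divergence;
divergence retracts the anterior boundaries (a frontal blind wedge appears)
while extending the posterior ones.

What the simulator does *not* emulate: marker mislabeling and occlusion
structure (dropout is i.i.d.), eye kinematics beyond a bounded offset,
body/wing obstruction of the perimeter, multiple birds, and experimenter
behaviour beyond the object path.  Passing tests therefore demonstrate that
the pipeline recovers what it models — poses, saccades, dwell, scores —
under realistic noise, not that real recordings are free of those
unmodelled effects.

## Problem sizes in the test suite

The suite simulates sessions of 2–10 trials (25–120 s at 120 Hz), uses 30
seeded sessions for the end-to-end dwell-recovery check and 100 seeded
replicates for the throw-vs-still score ordering, 10⁴ random rigid motions
for pose-recovery exactness, and 4×10³ trials for the noise-covariance
Monte Carlo — sizes at which every statistical tolerance in the tests is
set by the corresponding analytic or simulation oracle.

## Known limitations

* The packaged mean field is a constrained reconstruction (see above); its
  fine boundary shape should not be quoted as measurement.
* The multi-view reconstruction assumes annotated correspondences and given
  intrinsics; there is no feature detection and no lens model beyond two
  radial coefficients.
* Amplitudes of saccades that straddle untrackable gaps are measured across
  the gap's bounding poses and may be underestimated.
* The equirectangular heatmap is a visualization convention, not an
  area-faithful density; use the solid-angle region areas for inference.
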