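# Methods

This document describes the measurement model and the numerical choices made
by `chestmorph`. All lengths are in centimetres, times in seconds, and
coordinates live in the camera frame: the depth axis `z` increases away from
the camera, so the examination table lies at `z = d` and the torso is
displaced toward the camera (smaller `z`).

## 1. Input data

A recording is a sequence of colorized point clouds (binary PLY, `x y z`
float plus `red green blue` uint8) at a fixed frame rate (default 30 fps),
indexed by a JSON manifest (`format: chestmorph-sequence/1`, units `cm`,
`frame_rate_hz`, ordered frame list). The patient lies supine; three circular
matte fiducial markers (radius ≈ 1 cm) are placed on the left nipple, right
nipple and navel.

## 2. Marker detection and tracking

Each cloud is orthographically projected onto the x–y plane at a 0.1 cm/px
pitch (`pixel_pitch_cm`); per-pixel color is the mean of the contributing
points. Markers are far more color-saturated than skin or table, so the
HSV saturation channel is thresholded and a Hough circle transform is run in
a small search window (radius `search_radius_cm` = 2 cm) around the expected
position. The expected position is the operator's click on the first frame
and the previous frame's detection afterwards; frame-to-frame marker motion
(breathing, ≤ 1 cm) is far below the search radius. Candidate radii span
`marker_radius_cm ± hough_radius_tolerance` (1 ± 0.5 cm); a detection is
accepted if the normalized accumulator peak exceeds `hough_score_threshold`
(0.3), otherwise processing stops with an error naming the marker and frame.
The marker's `z` is the mean depth of the cloud points inside the detected
disc; only the x–y coordinates enter the alignment, so the small depth bias
of a disc centroid on a curved surface is immaterial.

## 3. Table plane and body-frame alignment

The operator specifies one or more boxes containing only table surface
(best: strips on all four sides of the patient, so both tilt axes are
constrained). A plane is fitted to the union of the box contents by SVD and
refined by iterative robust trimming: residuals more than 4 robust standard
deviations (1.4826 × MAD) from their median are discarded and the fit
repeated, at most 10 times. This tolerates clutter clipped by a box —
e.g. torso-taper points swept in when a yawed recording's axis-aligned box
circumscribes the true table strip. The fit fails loudly if fewer than
`min_table_points` (100) remain or the final rms residual exceeds
`max_plane_residual_cm` (0.5).

Each frame is then mapped by the rigid transform that (i) sends the table
normal to +z, (ii) makes both nipples share one x-coordinate with the navel
at larger x, and (iii) puts the mid-nipple point at x = y = 0. After
alignment, anatomy — not camera placement — defines the coordinate system.

## 4. Channel grid and depth-variation signals

A 7 × 7 grid spans the chest: rows 1…7 from the nipple line to the navel,
columns 1…7 from the left to the right nipple. Each channel is a 2 cm square
(`roi_half_size_cm` = 1). For every frame and channel the depth variation is
`r = d − mean(z)` over the points in the ROI — the height of the chest above
the table. The monitored channels are the three cross-section rows
(`rows_of_interest` = 1, 3, 5 → CS1, CS2, CS3) and the central channel
(4, 4), whose signal drives breath segmentation.

## 5. Breath segmentation

The central signal is low-pass filtered with a 4th-order Butterworth at
1 Hz (`filter_order`, `filter_cutoff_hz`), applied forward–backward
(`sosfiltfilt`) so extrema do not shift. Local extrema are detected with
plateau handling (a flat top registers at its leftmost sample), endpoints
are never extrema, and runs of same-type extrema are collapsed to the most
extreme one so minima and maxima strictly alternate. Each span between
consecutive minima is one breath; its period is the span length, its
amplitude the central maximum minus the mean of the two bounding minima.
The same index triples cut every channel, so all channels always carry the
same number of breaths.

## 6. Artifact detection and removal

Patient motion produces broadband transients. Each monitored channel's raw
(mean-removed, unsmoothed) signal is analyzed with a continuous wavelet
transform using ψ(t) = exp(−t²)·cos(π√(2/ln 2)·t) — a Gaussian envelope
whose oscillation makes the frequency response one octave wide at half
power — over 64 log-spaced scales covering 0.05–5 Hz (`cwt_n_scales`,
`cwt_freq_min_hz`, `cwt_freq_max_hz`), with reflect padding and 1/√a
normalization. The per-sample criterion is the scalogram magnitude summed
across scales; samples exceeding the channel's 99th percentile
(`artifact_percentile`) are flagged.

The merged mask is the union of all channels' flags, dilated by ±1 s
(`artifact_dilation_s`): the percentile rule marks only the crest of the
wavelet response, which for a sustained event (e.g. a step displacement)
can sit well inside the event while its flanks stay under the threshold, so
the contaminated span extends about one breathing-band time constant beyond
the crest. Every breath whose span touches the merged mask is removed, on
all channels alike. Note the rule is relative by construction — the top 1%
of samples is always flagged, even in a clean recording; this trades a
known, bounded loss of clean breaths for sensitivity that needs no absolute
motion threshold.

## 7. Breath gating

Each retained breath contributes a feature pair (period, amplitude). A
session's features are modeled as a bivariate Gaussian (sample mean and
covariance; a tiny ridge is added if the covariance is singular, as happens
for deterministic recordings). A breath's membership is the χ²(2) tail
probability of its squared Mahalanobis distance; breaths with membership
below `membership_floor` (0.05) are rejected. When two sessions are
compared, a breath must pass both sessions' models, so both sessions keep
only mutually comparable breathing.

## 8. Cross-sections, outliers, representatives

For every gated breath, the 7 node depths of grid rows 1/3/5 at the breath's
central maximum (inspiration) and at its closing minimum (expiration) form
transverse cross-sections CS1–CS3. Within each group (level × phase),
per-node Tukey fences at quartiles ± 1.5 IQR (`iqr_factor`) flag outlier
members in a single detection pass; a flagged time sample is then propagated
as an outlier at every level, so the levels always describe the same set of
time samples. At least 4 members per group are required for quartiles.

The cross-section area is the exact trapezoid integral of the
piecewise-linear depth profile. The representative of each phase is the
medoid of the clean (CS1, CS2, CS3) area triplets — the triplet minimizing
the summed Euclidean distance to all others, ties broken to the earliest
sample — so the representative is always a really-measured curve, never a
synthetic average.

## 9. Metrics

- Reliability: per-node CV and area CV over the clean members of each group
  (sample standard deviation, ddof = 1, as a percentage of the mean).
- Chest mobility (within a session):
  `Dsess = 100 · (A_insp − A_exp) / A_exp` per level, from the
  representative areas.
- Morphology change (between sessions, per phase):
  `D = 100 · (A_sess2 − A_sess1) / A_sess1` per level, from the
  representative areas after joint gating.
- Cohort comparison: per-subject paired values are tested with Shapiro–Wilk
  in each group; if both look normal at α = 0.05 a paired two-sided t-test
  is used, otherwise the Wilcoxon signed-rank test. Identical groups are
  reported as degenerate (p = 1) with a warning.

## 10. Synthetic phantom

Validation uses a synthetic supine-torso generator with exact ground truth
(`chestmorph.phantom`):

- geometry: a planar table at 53 cm; a torso dome whose peak depth follows a
  piecewise-linear profile over the 7 grid rows (default 6.0 → 7.0 cm,
  abdomen deeper than chest) multiplied by a lateral plateau-with-cosine-
  taper window; a point lattice at 0.25 cm pitch, offset by half a pitch so
  no lattice point ever lies exactly on a channel-ROI edge (knife-edge
  inclusion would otherwise flip with numerical jitter);
- breathing: raised-cosine cycles with per-cycle period jitter (default
  3 ± 0.3 s), per-cycle amplitude gain scatter (±10%), and end-expiratory
  baseline scatter (±5% of amplitude) cosine-eased between cycle starts so
  minima remain at cycle boundaries; per-row amplitudes default to
  0.2 → 0.8 cm from chest to abdomen;
- rendering: saturated circular marker patches at the nipples/navel,
  low-saturation skin, gray table; i.i.d. Gaussian depth noise (default
  σ = 0.05 cm); a configurable rigid camera pose (tilt, yaw, offset);
- artifacts: step-shift, spike or drift events over a time window,
  optionally restricted to grid rows/columns, injected into the clouds with
  exact masks recorded in the ground truth.

The ground truth exposes the clean per-channel signals, true marker tracks,
true extrema indices and artifact masks, so every pipeline stage can be
checked against a closed-form answer. Known simplifications: the torso is a
smooth dome (no ribs, clothing folds or arms), noise is i.i.d. Gaussian
(real depth cameras have range- and angle-dependent error), markers are
perfect circles, and the pose is constant within a recording.

## 11. Validation scenarios

`chestmorph.scenarios` fixes the study conditions used by both the
acceptance tests and `scripts/acceptance.py`: pose-invariance trials with
random tilt/yaw/offset; a deterministic 1.5 cm / 4 s signal-recovery trial
(15 cycles in 60 s, closed form); an artifact trial whose two injected
events jointly touch every monitored channel; a 2 min gating trial at a
young child's 25 breaths/min; a morphology pair whose static profile and
breathing amplitudes are scaled together so every cross-section area grows
by exactly the configured percentage; a mobility trial with amplitude a
fixed fraction of the profile; and a noise-degeneracy trial whose 4 s cycle
is an exact 120-sample period, making every breath sample-identical at zero
noise (all CVs exactly 0).

Scenarios that measure signal-level properties (amplitude recovery, cycle
count, noise propagation into CVs) are evaluated at the segmentation stage
(`run_phantom_breaths`), because the always-on percentile artifact rule
flags the top 1% of even a clean periodic criterion and, on deterministic
trials, can scatter those flags across every cycle. The artifact-removal
and gating stages have their own dedicated scenarios.
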