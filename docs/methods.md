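# Methods

## Motion model and measurement chain

Each condyle's motion within an imaging plane is reduced to a scalar
displacement: the centroid of the segmented condyle, projected onto an
anatomical reference line (mid-sagittal line in the axial plane, Frankfurt
horizontal line in the sagittal planes), relative to the position at the
start of the series.  The sign convention makes the dominant excursion —
jaw opening — positive.  Opening and closing phases are the rising and
falling segments between alternating displacement extrema; all symmetry
parameters are computed per matched right/left phase pair and then
averaged per phase kind across cycles.

Reference lines are inputs (from configuration or the phantom's known
geometry), not detected: automatic anatomical landmarking is out of scope.
Side assignment in axial frames uses the mid-sagittal line under
radiological orientation — the component on the image left is the
subject's right condyle.  The image handedness convention matters and is
therefore stated explicitly wherever it is used.

## The synthetic phantom

The phantom emulates slow, repeated jaw open/close cycles of ~5 s per
phase, the subject reaching maximal amplitude each time, imaged as:

* one axial series, both condyles, frame period 21 ms, 1.41 mm pixels,
  192 mm field of view;
* two sagittal series acquired by alternating slices, one condyle each,
  51 ms per image — so each side is sampled every 102 ms, the left series
  offset 51 ms from the right — 0.36 mm pixels, 100 mm field of view.

The sagittal per-image period is a free parameter rather than being
derived from TR × spokes, because the acquisition protocol's stated
sagittal timing does not equal that product; the axial period does
(⌊2.34 × 9⌋ = 21 ms) and is exposed as `nominal_frame_period`.

Displacement per phase is a raised-cosine position ramp,
d(t) = A·(1 − cos(πt/T))/2: smooth, zero endpoint velocity, closed-form
speed peak πA/2T at mid-phase.  The default amplitude is 15 mm, a typical
maximal condylar translation.  Injected asymmetries on the configured
lagging side:

* **Onset latency** delays the lagging side's phases by
  `latency_fraction × T` with phase durations preserved, so the measured
  normalized latency equals the injected fraction exactly.  With
  back-to-back cycles, displacement continuity forces the opening and
  closing onset delays to be equal in absolute time when more than one
  cycle is simulated; the configuration validator enforces this.
* **Velocity-peak delay** reparameterizes the phase with a C² monotone
  time warp φ(u) = u − v·g(u), where g is a quintic-smoothstep bump equal
  to 1 exactly at u\* = 0.5 + v.  The speed is proportional to
  sin(πφ(u)), which peaks exactly at u\*.  The warp being C² matters: a
  peak with discontinuous slope or curvature is displaced by any symmetric
  smoothing filter, which would make the generator's ground truth
  unrecoverable by a correctly implemented pipeline.  The warped ramp has
  no closed form and is tabulated by dense cumulative integration
  (4097 points, cached per shift).  Side effect: the warp perturbs the
  10 %-velocity onset by O(v³), so a VPD-only phantom shows a negligible
  but nonzero latency.
* **Amplitude difference** sets the per-side amplitudes independently.

Noise is additive Gaussian on displacement samples (the tracking stage
consumes centroids, not raw k-space, so Rician image-domain noise is not
modelled); image series get separate additive Gaussian noise of
sd 1/SNR on a 0/1 foreground.  What the phantom does **not** emulate:
through-plane motion, head motion between series, segmentation failures
other than threshold dropouts, partial condyle visibility, reconstruction
artifacts, or within-subject cycle-to-cycle variability.  Passing the
recovery suites therefore demonstrates the correctness of the measurement
chain under controlled conditions, not clinical performance.

In the axial phantom the two condyles are placed mirror-symmetrically
about a pixel-aligned mid-sagittal line, so a symmetric configuration
rasterizes to exactly mirrored masks and the null suite is exact rather
than rasterization-limited.

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| segmentation threshold | 0.5 | phantom foreground is 1, background 0 |
| minimum component area | 20 px | rejects noise specks smaller than any condyle |
| gap interpolation limit | 5 frames | bounded, testable dropout policy; longer gaps invalidate the track |
| minimum track validity | 80 % | below this the series is unusable |
| smoothing window | 1100 ms, order 2 | ≈11 frames at the sagittal per-side period; expressed in time so the 5×-faster axial series is smoothed over the same physical window |
| onset threshold | 10 % of peak speed | standard onset definition for this measurement |
| phase prominence / duration | 2 mm, 500 ms | well below the smallest plausible opening amplitude and duration |
| latency resolution floor | half the coarsest frame period | onset differences below temporal resolution are reported as 0/none |
| 3DTC threshold | 1 mm | per-axis amplitude difference considered clinically visible |

## Numerical choices

* **Smoothing** is Savitzky–Golay (local least-squares polynomial), with
  endpoints handled by the polynomial fit on the truncated window
  (`mode="interp"`).  Velocity is the central finite difference of the
  smoothed displacement on the actual timestamps, one-sided at the ends.
* **Onset** is located by linear interpolation of the speed between the
  two samples bracketing the threshold crossing.
* **Velocity-peak time** is the vertex of a least-squares parabola fitted
  to the samples within 95 % of the discrete peak speed, truncated to a
  window symmetric about the peak sample and clamped to it.  The wide fit
  averages noise; the symmetric truncation prevents the vertex from being
  dragged toward the flatter flank of an asymmetric speed profile.
* **Normalization of temporal parameters** divides by the mean of the two
  phase durations — symmetric in the sides, and equal to the common
  duration when they agree.
* **MDD origin**: each side's displacement is referenced to its own
  phase-start position.  The condyles sit ~100 mm apart, so the literal
  inter-condylar distance cannot be the intended quantity; MDD compares
  motion, not anatomy.  Both the mm value and the series-amplitude
  normalized value are reported.
* **Phase matching** is greedy by temporal overlap within each phase
  kind; unmatched phases are simply not paired.
* **Degenerate inputs**: a flat phase (zero peak speed) is an error;
  normalized temporal parameters above 1 are clipped to 1 with a warning;
  kappa with both raters constant and identical returns 1 by convention;
  Spearman on constant input is an error; correlation-matrix cells with
  fewer than 3 complete pairs are flagged missing.
* **3DTC tie-breaks**: when exactly one axis exceeds the threshold the
  score is 0 (the asymmetric score is defined by "at least two axes");
  when the exceeding-axes amplitude sums tie, the side with the smaller
  total amplitude lags, then the left by convention.
* **Fusion**: ML is the axial coordinate orthogonal to the mid-sagittal
  line, CC the sagittal coordinate orthogonal to the Frankfurt line, AP
  the mean of the two planes' projections after sign alignment (the two
  series are acquired separately and carry no shared handedness).  All
  relative to each track's first sample, making fusion invariant to
  constant offsets.  An RMS disagreement of the two AP projections above
  3 mm is recorded as a warning, not an error — the planes are acquired
  in separate motion repetitions and some variation is expected.
* **Determinism**: one root seed per run, forked per stage by a CRC of
  the stage name; all tables are written with fixed float formatting,
  UTF-8 and LF newlines, so identical configurations yield byte-identical
  artifacts.

## Interpretation bands

Two kappa band tables ship: a Landis–Koch-style table (default: 0–0.20
slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial,
0.81–1.00 almost perfect) and McHugh's table, selectable in
configuration.  The default is the scheme whose labels match how kappa
values in this range are conventionally reported in the TMJ imaging
literature.  Spearman labels follow Schober's guidance (0.10/0.40/0.70/
0.90 cut-points) applied to |ρ|.  For rater agreement, both the binary
score and an ordered three-level encoding (lag-left < none < lag-right)
with linear weights are supported; averaging two binary raters resolves
0.5 ties toward the asymmetric score.

## Problem sizes used in validation

The test and acceptance suites run the image-level pipeline on 2-cycle
phantoms (≈20 s of motion: ~950 axial frames of 136², ~200 sagittal
frames of 278² per side) and the signal-level recovery suites on 3-cycle
displacement signals at the axial frame period, 20 noise replicates per
injected value — sizes chosen so the full validation completes in a few
minutes on one CPU while matching the acquisition's frame geometry.

## Known limitations

* The stand-in segmenter is a global threshold plus component filtering;
  it is adequate for phantom images and is not a substitute for a learned
  segmenter on clinical images.
* Aggregation across cycles is the arithmetic mean; real protocols may
  prefer a single representative cycle.
* The 3D fusion assumes the two acquisitions share the anatomical axes up
  to sign; no inter-series rigid registration is performed.
* Latency and VPD estimates interact when both asymmetries are injected
  simultaneously (the onset threshold is relative to the — shifted —
  peak speed); recovery guarantees are stated per asymmetry in isolation.
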