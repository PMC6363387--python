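# Methods

This note records the models implemented by `recastate`, the meaning
and defaults of the parameters that matter, what the synthetic-data
generators do and do not emulate, and the numerical conventions and
known limitations of each stage.

## Two-state smFRET model

A surface-immobilized DNA substrate carries a donor/acceptor pair whose
FRET efficiency reports RecA-filament occupancy of the ssDNA overhang:
an unbound substrate sits at efficiency 0.43 and a filament-bound
substrate at 0.20 (both with observed width 0.07). The generative model
(`TwoStateKineticModel`) is a continuous-time alternating renewal
process: unbound dwell times are exponential with pseudo-first-order
binding rate `k_bind` (default 0.2 s⁻¹); each binding event is assigned
to a slow-dissociating class with probability `f_slow` (default 0.91)
and its bound dwell drawn from `Exp(k_off_slow)` (0.044 s⁻¹), otherwise
from `Exp(k_off_fast)` (0.23 s⁻¹). The class assignment is per event,
not per molecule, so pooled dwell times follow the static mixture
survival `S(t) = (1−f_slow)e^(−k_fast t) + f_slow e^(−k_slow t)`.

The state sequence is discretized at the camera frame interval
(default 0.1 s) by majority occupancy within each frame, mimicking
camera integration. Emission: the per-frame FRET value is drawn from
the occupied state's Gaussian; donor and acceptor intensities are
reconstructed from that value and a noisy summed intensity
(mean 400 counts, shot-like sd `intensity_noise·√total`), with a
donor→acceptor crosstalk term `I_A = E·I_tot + c·I_D`. Because
intensity noise enters through the sum, the acceptor/total ratio — and
hence the FRET value recovered after crosstalk correction — reproduces
the drawn emission exactly; the state widths are therefore widths of
the *observed* FRET distribution, which is how histogram widths are
measured in practice. Traces start unbound; the first and last episodes
are censored.

### Analysis chain

* `compute_fret`: `E = (I_A − c·I_D) / ((I_A − c·I_D) + I_D)`; frames
  with non-positive corrected total are flagged invalid; E clipped to
  [−0.5, 1.5] with a flag. The crosstalk coefficient defaults to 0 and
  is a configuration field — the correction formula is fixed but its
  magnitude is instrument-specific.
* `fit_fret_mixture`: expectation–maximization on raw values (sklearn
  Gaussian mixture for the free fit). When state positions are known
  from calibration (substrate alone, saturating filament), means —
  and optionally widths — can be pinned, leaving only the weights free;
  this fully calibrated variant is what `analyze_titration` uses,
  because with free widths the weight of the minority component at the
  titration extremes is biased upward by a few percent, which steepens
  the recovered Hill curve (cooperativity +0.1 to +0.2). A histogram
  least-squares fit is provided for figure parity; the EM fit is
  bin-independent and is the default.
* `fit_hill`: least squares of `f(c) = cⁿ/(cⁿ + K_Dⁿ)` with baseline
  fixed at 0 and saturation at 1 (the inputs are normalized mixture
  weights); uncertainties are the fit covariance. Requires ≥4
  concentrations spanning the transition.
* `segment_states`: a frame is bound iff `E < 0.3` (strictly; E equal
  to the threshold is unbound). Adjacent same-state frames merge;
  boundary segments are censored; invalid frames inherit the previous
  frame's state; minimum dwell is one frame, with no sub-frame
  interpolation. Segments tile the trace exactly.
* `fit_survival_biexp`: least squares of the two-exponential survival
  against the empirical survival (complement of the cumulative
  residence-time distribution), weighted by the binomial uncertainty
  `√(S(1−S)/n)`; censored dwells are excluded by default, avoiding
  censoring-bias machinery at the cost of discarding the longest
  events. A single-exponential fit and an AIC difference are reported
  so degenerate (single-rate) data can be recognized.

### Sampling properties worth knowing

* At `f_slow = 0.91` only ~9% of events carry fast-rate information: a
  single 5000-dwell sample determines `k_fast` with ~22% sd whatever
  the estimator. The estimator is median-unbiased, so recovery checks
  aggregate medians over replicate samples.
* Threshold segmentation at the default emission widths misclassifies
  bound frames with probability Φ((0.3−0.2)/0.07 sided) ≈ 7.6% and
  unbound frames ≈ 3.2%; frame-label accuracy on a mostly-bound trace
  is therefore bounded near 93%, and long bound dwells are fragmented
  by noise crossings. Off-rate recovery from trace segmentation
  consequently requires either higher frame-level SNR than the default
  emission widths or dwell-time samples taken from the generator's
  ground truth; the tests use the analytic expectation for label
  accuracy and ground-truth dwells for rate recovery.
* Frame quantization biases recovered rates low as `k·Δt` approaches 1
  (dwells shorter than a frame are unobservable); the bias is monotone
  in `Δt` and is covered by a test.

## Synthetic cell fields

`simulate_cell_field` renders spherocylindrical cells (length 2.2–4 μm,
width 0.9–1.1 μm) on a jittered grid with random orientation, at
0.1067 μm/px (from the 25 px² = 0.28462 μm² focus-footprint
calibration). Channels:

* **Brightfield**: dark cell bodies (depth 400 below a 1000-count
  background), blurred by a σ = 1 px PSF, Gaussian read noise sd 8 —
  about 0.8% of background, typical of a 100-ms exposure.
* **Focus channels "a"/"b"**: slide background 479 au, cytosol
  1576 au; foci are Gaussian spots (σ 1.3 px, amplitude 3000 au) drawn
  at their own PSF width on top of the blurred cytosol (they are
  PSF-sized images of point emitters, so they are not re-blurred).
  Counts per cell are Poisson (defaults 2.0 and 1.5); within-channel
  separation is kept at 0.45 μm so ground-truth foci are countable as
  distinct objects. Colocalization labels are assigned by stratified
  permutation over all channel-b foci in cells with at least one
  channel-a focus, so the configured colocalized fraction is realized
  exactly; colocalized foci are placed within 0.5× the colocalization
  radius of an a-focus, non-colocalized ones at least 1.5× the radius
  away. Placement that cannot satisfy the label-critical clearance
  raises an error naming the constraint.
* **GFP channel**: cytosol plus elliptical polar storage structures
  (intensity 8615 ± 1000 au, target maximum Feret diameter drawn
  1.0 ± 0.2 μm), matching the measured background/cytosol/structure
  intensity calibration.

`simulate_timelapse` renders the GFP channel over 37 frames at 5-min
intervals. Cytosolic intensity follows a logistic SOS-induction-like
fold-increase curve (baseline 1, amplitude 1 → two-fold peak, midpoint
60 min, width 15 min); amplitude 0 gives a flat series. Initial
structures dissolve with probability 0.56 at lognormal times
(median 45 min, log-sd 0.5) — their intensity drops to cytosol level at
the event frame — and cells gain a new structure at the opposite pole
(lognormal median 90 min) unless the newcomer would fuse with an
existing footprint, in which case it is skipped (a merged blob is not a
countable new object). Ground-truth event times are recorded at frame
resolution.

What the generators do **not** emulate: optical PSF structure beyond
Gaussian spots, phase effects in brightfield, cell growth/division and
crowding/overlap, expression heterogeneity between cells,
photobleaching (off by default; traces are 2–3 min), PALM
photoactivation kinetics, and replisome biology. Passing tests
demonstrate that the analysis chains recover known ground truth under
these idealized conditions; they do not certify performance on real
images with touching cells or structured backgrounds.

## Cell segmentation

The chain is bandpass → edge → ridge with the calibrated parameters
(bandpass large/small = 2/0 px, edge smoothing 2 px, ridge line width
2 px, σ = 0.8, hysteresis thresholds 1.7/5 on the 8-bit edge image,
contrast saturation bounds 230/87 retained as configuration for
automatic threshold estimation). Implementation details:

* The bandpass is a difference of Gaussians (σ = cutoff/2), the
  Fourier-domain Gaussian band; DC is removed whenever the large-
  structure cutoff is active.
* The edge map is the Gaussian-derivative gradient magnitude, linearly
  rescaled so its maximum maps to 255 — the ridge thresholds are
  calibrated to 8-bit intensities.
* Ridge points come from Hessian eigen-analysis: the eigenvector of
  the largest-magnitude eigenvalue is the across-line direction, and
  the first directional derivative locates the line to sub-pixel
  accuracy (accepted when the offset stays within the pixel).
  Detected centerlines of isolated synthetic lines are accurate to
  ~0.02 px RMS.
* Linking: strongest points are traced first so salient contours claim
  their pixels before weaker crossing spurs; candidates must continue
  roughly along the local tangent (junction spurs fail this); holes of
  up to ~2.5 px are jumped along the travel direction; traced chains
  are stitched end-to-end across ≤3 px gaps; and long chains whose
  ends face each other across ≤12 px are closed with a
  tangent-following Bézier arc. These choices implement the junction
  ("slope") resolution and line-extension behaviors of the original
  detector in intent, not bit-exactly.
* Coordinates: pixel centers at integer positions, origin top-left,
  x = column; areas by the shoelace formula on sub-pixel polygons;
  chains shorter than 10 px are discarded as noise fragments.

Known limitation: on a blurred curved boundary the gradient-magnitude
maximum sits slightly inside the true edge, so detected outline areas
run ~5% low systematically (well inside the 10% evaluation band).
The bandpassed step edge also produces weaker secondary ridges a few
pixels on either side of the boundary; they are usually rejected by
closure and best-overlap matching but can surface as concentric
contours.

## Foci and colocalization

Detection threshold is per-cell `median + k·MAD` (default k = 6) over
background pixels. Because diffraction-limited spots can cover a large
fraction of a small cell, background pixels are identified first: a
pooled robust pass (field-level lower-quartile location with lower-tail
MAD) flags candidate spots, whose dilated footprints — and a 2.5-px
boundary skirt — are excluded from the per-cell statistics; cells with
no clean background fall back to the pooled threshold. Maxima are
refined by intensity-weighted centroid over a background-floored 5×5
window (~0.4 px median error), merged to the brighter peak within the
minimum separation, and assigned to cells by point-in-polygon.

Colocalization uses centroid distance ≤ 0.2 μm within the same cell,
restricted to cells with at least one focus in both channels;
per-cell fractions are averaged and reported with SD and SEM across
qualifying cells. The chance null multiplies per-channel coverage
probabilities `P = n·N·A_focus/ΣA_cells` with the 0.28462 μm² focus
footprint; the distance rule and the footprint area are deliberately
different conventions (radius on centroids vs area coverage), used
side by side. The analytic null agrees with uniform-placement
Monte-Carlo simulation to within ~13% at focus coverage ≤0.15 (it
ignores focus overlap and edge effects, so it drifts high at higher
densities).

## Population intensity and storage structures

The population statistics implement the printed conventions exactly:
`F_i` is the mean of per-cell area×intensity products; the spread takes
deviations from the *product of the means* `Â·Î` (not the mean of the
products) divided by `K−1`; the error of the mean is `σ/K` (not
`σ/√K`); and the fold-increase error is the additive `ΔF_i + ΔF_0`.
A conventional first-order ratio propagation is available behind
`corrected_errors=True`, but the printed form is the default for
parity. Timepoints with a single cell have undefined spread and are
flagged rather than rejected.

Storage structures are 8-connected components of pixels ≥ threshold
inside a cell, minimum 4 px. The thresholds 4000 au (standard) and
1200 au (low-expression strains) are named presets — they are
camera-specific arbitrary units, not portable constants. The maximum
Feret diameter treats the region as a union of unit squares: the
convex hull of pixel corner points followed by an all-pairs scan of
hull vertices (rotating-calipers equivalent at these sizes), so a
single pixel has diameter √2·pixel_size. The corner convention is
chosen over pixel centers so single-pixel regions have nonzero extent.

Event tracking follows structures detected in the first frame on their
initial footprint: the dissolution time is the first frame whose mean
footprint intensity falls within 2 SD of the cell's cytosolic
background (background = in-cell pixels outside tracked footprints and
below the detection threshold; the 2-SD rule operationalizes
"indistinguishable from background", for which no numeric rule is
printed). Detections in later frames that overlap no known footprint
at ≥30% Jaccard are new structures with their first frame as the
appearance time. The bookkeeping identity (initial = dissolved +
persistent; total = initial + appeared) is enforced by construction
and tested.

Event-time CDFs are empirical CDFs on the frame-quantized time grid;
per-gridpoint errors are standard deviations over 1000 resamples of
80% of the data, drawn without replacement (the resampling fraction
and count follow the stated protocol; with/without replacement is not
stated — without was chosen, making the degenerate single-value case
exactly zero-spread). The half time is the first gridpoint at which
the CDF reaches 0.5; it is reported at frame resolution (±5 min at
5-min intervals), so a process with its median exactly on a grid point
can legitimately report the neighboring frame.

## Determinism and I/O conventions

Every generator takes an integer seed (or an explicit
`numpy.random.Generator`); identical configuration and seed give
bit-identical outputs. Output tables carry coordinates in μm with
pixel provenance columns, origin top-left, 0-based frame indices,
minutes for time-lapse and seconds for FRET. `write_results` emits CSV
tables plus a manifest with a configuration hash, seeds and the
package version, so reruns are auditable. The command line
(`recastate`) is a thin wrapper over these functions.
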