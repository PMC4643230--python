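# Methods

## Overview

`caflux` quantifies global intracellular Ca²⁺ responses of non-excitable
cells (e.g. Fluo-4-loaded lymphocytes) from single-channel time-lapse
fluorescence movies. Cells in suspension drift above a stimulating
surface, land (an immediate cessation of movement plus a small intensity
step as the cell reaches the focal plane), and a subset then releases
calcium: the indicator fluorescence rises sharply within seconds and
decays slowly over tens of seconds. The pipeline reduces each movie to
per-cell response curves R(t) = I(t)/Imax, classifies responders,
measures triggering intervals T = t_triggering − t_landing, and
aggregates population statistics.

The processing chain is fixed: segmentation → tracking → landing
detection → inclusion filters → trace extraction → Savitzky–Golay
smoothing → (optional resampling) → normalization → derivative-peak
event detection → classification → population summary.

## Segmentation and tracking

Candidate cells are detected per frame: Gaussian pre-smoothing (σ = 1 px),
thresholding, connected components, area gate. The default threshold is
the frame median plus five robust (MAD-based) standard deviations; this
is deliberately not a bimodal-histogram method (e.g. Otsu), because a
handful of very bright triggered cells — up to two orders of magnitude
above baseline — dominates the histogram and would push an Otsu cut
above the dim pre-landing cells. Otsu remains selectable
(`detect_threshold: otsu`).

Each component is then cut at its half-maximum above background before
measuring anything. Thresholding alone keeps the blur "skirt" of bright
cells, and because the skirt grows with brightness it dilutes the mean
intensity more at the response peak than at baseline, biasing the
fold-increase dI/I0 downward. The half-max contour of a blurred
uniform disk sits at the true cell boundary independent of brightness,
so mask geometry — and hence I(t) — is brightness-invariant.

Detections are linked frame-to-frame by nearest-centroid association
with a step gate of one cell diameter per frame. When two tracks claim
one detection within the gate (cells whose boundaries merge), both are
flagged as overlapping and later excluded. A track unmatched for more
than 5 frames is closed; unmatched detections open new tracks.

Landing is the first frame from which the per-frame displacement stays
below `motion_stop_threshold` (0.5 px/frame) for `motion_stop_frames`
(5) consecutive frames and the cell never moves again and remains in
view to the end of the movie. The thresholds are package defaults, not
measured values; they assume centroid jitter well below half a pixel
for a stationary ~100-pixel cell at typical SNR. A track that is first
seen mid-movie already stationary is assigned no landing: no cessation
of movement was observed, and such tracks are typically re-detected
fragments after an overlap event.

Inclusion filters mirror the standard analysis: cells must land within
the first 300 s (`landing_window`), sit at least one cell diameter
(`edge_margin_diameters`) from the field edge at landing, never overlap
another cell, and have a landing at all. Counts per exclusion reason
are logged and written to the run manifest.

A distance-regularized level-set (DRLSE) refiner is provided for
boundary-accurate masks (`caflux.drlse`). It implements the standard
edge-based energy — double-well distance regularizer, edge-weighted
length and balloon terms — with defaults μ = 0.2, λ = 4, α = −1.5
(inflation), σ = 1.5 px, 300 iterations, Δt = 1 (stability requires
μ·Δt < 0.25). The edge indicator normalizes the gradient magnitude by
its 99.9th percentile; without this, a sharp high-contrast edge drives
the indicator to ~10⁻⁴ and the evolution stalls about a pixel short of
the boundary. On noise-free disks the refined mask reaches IoU ≥ 0.95
against truth, ≥ 0.8 at SNR ≈ 5, and the narrow-band mean ||∇φ|−1|
stays below 0.2 — the defining distance-regularization property. The
refiner is not run per frame inside the default pipeline: the half-max
masks are already boundary-accurate for disk-like cells at a tiny
fraction of the cost, and mean-intensity traces are insensitive to
single-pixel boundary differences (see pixel-count robustness below).

## Traces

I(t) is the arithmetic mean of the raw camera counts over the cell's
mask in each frame. Frames missed by detection inside a track are
filled by linear interpolation and logged. Smoothing is Savitzky–Golay
(window 7 frames, order 2 by default; the smallest window that
suppresses single-frame shot noise at 2 Hz without flattening a 2–5 s
rise). Edges are handled by evaluating the boundary window's
polynomial, so the filter reproduces polynomials up to the fit order
exactly.

Resampling to a coarser interval decimates (every k-th sample from
sample 0) when the target is an integer multiple of the native
interval — simulating a slower camera, which is the intended use —
and falls back to linear interpolation otherwise. Because the
decimation factors along the default scan ladder (0.5 → 1 → 5 → 15 →
30 → 60 s) divide each other, coarser sample sets are nested within
finer ones.

Normalization defines R(t) = I(t)/Imax with Imax the maximum of the
smoothed trace, so max R = 1 exactly. The baseline I0 is the median
over 9 samples starting at landing: a post-landing, pre-trigger
plateau. A pre-landing baseline was rejected because pre-landing cells
are out of focus and systematically dimmer (the landing step), which
would inflate dI/I0. dI = Imax − I0 and dI/I0 (the fold-increase over
background) are carried on every trace for classification and for
dye-loading robustness reporting.

## Event detection and classification

Both landing and triggering appear as peaks in dR/dt (central
differences on the uniform grid; one-sided at the ends). The landing
peak is small; the trigger peak is the largest local maximum after it
with prominence at least 3× the robust SD of the pre-landing
derivative (adaptive per cell, since a global floor would either miss
quiet cells or fire on noisy ones; a fixed value is configurable).
The triggering time is the onset of that peak — the interpolated
rising crossing of 10% of peak height — rather than the peak position,
since the quantity of interest is the beginning of calcium release.
With the default smoothing the onset estimate carries a small,
systematic early bias (≈0.8 s at 2 Hz, from the smoothing window's
backward smear), well within the ±1 s recovery tolerance verified on
synthetic movies.

A cell is a responder when (1) a trigger peak exists, (2) the
amplitude criterion holds — dI/I0 > `response_threshold` (default 5,
i.e. a >500% increase over background; the alternative reading
Imax/I0 > threshold is selectable) — and (3) R(t) subsequently
decreases, shedding at least `decrease_fraction` (default 0.2) of its
above-baseline excursion after the maximum. The decrease requirement
separates genuine transients (sharp rise, slow decay) from monotone
drifts; the 0.2 value is a package default. Raising the threshold can
only remove responders (monotonicity), and the entire classification
is invariant under global intensity scaling.

For presentation, trace time axes are aligned with t = 0 at 2 s after
landing (`align_offset`); alignment never affects classification.

## Population outputs

The responder fraction is n_responders/n_included with a binomial
s.d.m. √(p(1−p)/n). (The error convention throughout is s.d.m. —
standard deviation of the mean; plain SD is selectable.) The mean
response curve is the pointwise mean of aligned R(t) over responders,
using at each time point only the cells observed there and dropping
points covered by fewer than two cells. Triggering-time statistics
(mean ± s.d.m., histogram, boxplot) are computed over responders.

The resolution scan re-runs normalization, event detection and
classification on decimated traces for each requested interval and
reports the detected fraction; at the native interval it reproduces
the standard analysis exactly. The pixel-subsample report recomputes
R(t) from seeded random subsets of each cell's landing-frame mask and
reports the RMS deviation from the full-mask R(t). The dye-loading
report tabulates per-cell dI/I0 with group statistics, flagging cells
with non-positive baselines. The maximum-intensity projection is
rendered blue→red; cells that moved and then triggered appear as a
red dot with a blue tail.

## Synthetic scene generator

The generator is first-class, tested code: it renders movies of
uniform-intensity disks with per-cell ground truth (landing frame,
responder flag, trigger frame, amplitude, trajectory, masks) so that
every downstream stage is testable by parameter recovery.

What it emulates, and the defaults (all configurable):

- Field and sampling: 512×512 px, 600 frames at 2 Hz (0.5 s interval),
  emulating fast spinning-disk acquisition of a large field.
- Cells: 200 disks of radius 6 ± 0.8 px (≈113 px², comfortably above
  the 20-px detection floor and enough for 20-pixel subsampling).
  Initial centres are rejection-sampled with ≥2 mean diameters of
  separation so that boundary-overlap events stay rare (a few percent),
  as in an experiment run at a suitably chosen cell density.
- Motion: fixed-magnitude random-walk steps of 1 px/frame in a uniform
  random direction before landing, reflected at the field border (so
  no cell stalls against the edge and fakes a landing); strictly
  stationary afterwards.
- Landing: times uniform on 5–60 s; pre-landing intensity is the
  baseline divided by `landing_step_factor` (1.3), reproducing the
  relatively small landing step as the cell reaches the focal plane.
  The value is a free default, not a measured one.
- Transient: responders (fraction 0.6) fire once at a delay uniform on
  50–200 s after landing, with amplitude dI/I0 uniform on 5.5–20 and
  shape g(t) = (1 − e^(−t/τr))·e^(−t/τd) normalized to unit peak,
  τr = 3 s, τd = 40 s. The kinetics are assumptions chosen to match
  the qualitative phenomenology (sharp few-second rise, slow
  tens-of-seconds decay); repeated oscillations are out of scope.
- Noise: additive Gaussian (SD 2 counts) by default; Poisson optional.
  Baseline I0 = 100 counts on a zero background, 16-bit output.

Disks are rendered at the integer-rounded centroid with uniform
intensity, so with noise disabled each cell's rendered mean trace
equals its analytic transient to within 16-bit rounding (<1%
relative). Identical configurations (including seed) produce
bit-identical movies and ground truth. A responder whose drawn trigger
falls beyond the last frame is recorded as a non-responder (it is
unobservable in that movie).

What the generator does **not** emulate — and hence what passing
recovery tests do not show about real data: realistic optics (PSF,
out-of-focus light), photobleaching, intensity inhomogeneity within a
cell, cell deformation or division, sub-cellular Ca²⁺ sparks, or
empirical landing/kinetic distributions. Recovery results on synthetic
movies demonstrate the correctness of the algorithms under the stated
model, not performance on any particular instrument's data.

## Numerical choices and degenerate inputs

- Frame indices 0-based; times in seconds; pixel coordinates (row, col).
- Tracking ties (two tracks equidistant from one detection) resolve to
  the lower cell id; both claimants are still flagged as overlapping.
- Traces shorter than the smoothing window are dropped from analysis;
  resampling that would leave fewer than 4 samples is an error.
- Imax = 0 is a normalization error; I0 ≤ 0 excludes a cell from
  dI/I0 ratio statistics (flagged, not silently dropped).
- DRLSE divergence (contour vanishing or flooding >50% of the frame)
  raises an explicit error naming the parameter set.
- Writing intensities outside the unsigned 16-bit range is an error,
  not a silent clip.
- All stochastic steps (scene generation, pixel subsampling) take
  explicit seeds; the analysis itself is deterministic, and repeated
  runs produce byte-identical CSV outputs.

## Problem sizes used in the shipped checks

The test suite and the acceptance script exercise the full
512×512/600-frame/200-cell standard conditions once, and use smaller
seeded scenes (300×300 with 40–60 cells; 200–220 px fields with 10–15
cells) for per-module recovery, resolution-scan, robustness and
determinism checks. These sizes were chosen so the whole suite
completes in a few minutes while keeping ≥50–150 included cells in the
statistical assertions.

## Known limitations

- The tracker is nearest-neighbour with a gate: it does not resolve
  occlusions or re-identify cells after long gaps; merged cells are
  excluded rather than split.
- Landing detection assumes permanent arrest; a cell that lands,
  detaches and re-lands is not modelled and would be excluded.
- The trigger-onset estimate inherits a small early bias from
  smoothing (see above); at acquisition intervals ≳15 s onsets are
  quantized to the sample grid and T loses precision accordingly.
- Absolute Ca²⁺ concentrations and sub-cellular spark analysis are out
  of scope by design; R(t) is a relative, indicator-dependent readout.
- Mean R(t) is computed over responders only by default (an all-cells
  variant is available), and the binomial s.d.m. on the fraction
  reflects within-movie counting statistics, not between-experiment
  variability.
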