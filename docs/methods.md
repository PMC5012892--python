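# Methods

## Scope and data model

`phagoquant` analyses multi-well fluorescence time-lapse plates of the kind
produced by live-cell imagers running pH-switch (pHrodo-type) phagocytosis
assays. One acquisition plane is a `Frame`: a 2-D grid of non-negative
intensities plus well id, replicate image index, channel (`phase`, `green`,
`red`), time in minutes since assay start, and pixel size in µm. Frame files
follow the convention `{well}_{image_index}_{channel}_t{minutes}.tif`; the
convention is this package's own (acquisition vendors keep this in internal
databases) and was chosen to be deterministic, sortable and parseable
without sidecar metadata. Times are real minutes taken from filenames — no
fixed cadence is assumed. Pixel coordinates are 0-based `(row, col)`; areas
convert to µm² via `pixel_size_um**2`. Exposure times are treated as
acquisition metadata only and never rescale intensities, as no rescaling
rule is defined for these instruments' "corrected units".

## Segmentation chain

**Top-hat correction.** White top-hat by a flat disk of radius
`round(radius_um / pixel_size_um)` px (≥ 1 px, clamping with a warning),
default radius 20 µm. A flat disk is used because background non-uniformity
has no preferred direction. Border handling is reflection. The
implementation (scikit-image grayscale morphology) is validated exactly —
bitwise, not approximately — against a brute-force shift-enumerated
erosion-then-dilation oracle in the test suite.

**Threshold.** Foreground iff corrected intensity ≥ 2 corrected units. The
comparison is *inclusive*; assay software documentation does not state the
boundary semantics, so one choice had to be fixed and documented to make the
boundary testable. "Corrected units" are whatever units the input TIFF
carries after correction; no bit-depth assumption is made.

**Labeling.** 8-connectivity (consistent with the watershed neighbourhood),
relabelled so that label k's first pixel in raster order precedes label
k+1's — this makes object tables reproducible byte-for-byte.

**Edge split.** Vendor declumping algorithms are proprietary; the standard
method with the same observable behaviour (splitting touching blobs along
intensity valleys) is marker-controlled watershed. Seeds are local maxima of
the Gaussian-smoothed (σ = 1 px default) corrected image, separated by at
least the equivalent diameter of the minimum object area
(d = 2·√(A_min/π) / pixel size); regions with ≤ 1 seed pass through
unchanged, and the operation never moves foreground pixels between parents
or to background — the children of a region partition it exactly. Threshold
→ label → split ordering is fixed (the alternative, splitting before
thresholding, is not meaningful for watershed on a binary support).

**Area filter.** Objects strictly below 50 µm² are removed ("below" read
literally, so an exactly-50 µm² object survives). By default the filter is
applied to fluorescence objects as well as phase objects
(`apply_area_filter_to_fluorescence`); sub-bacterium dye aggregates are
noise in either channel. At 2 µm pixels this means objects need ≥ 13 px.

**Confluence mask.** Phase frames get a local-variance texture map (square
window of twice the top-hat radius), Otsu threshold, closing by a 2 px
disk, and small-component removal at the minimum object area. Otsu on a
unimodal variance map (pure sensor noise, no cells) splits arbitrarily, so
a contrast guard treats the frame as cell-free when the foreground class's
mean variance is below 3× the background class's; a constant image returns
fraction 0 with a warning. The confluence fraction feeds reporting only and
never enters fluorescence metrics. This whole stage is an invention of this
package — only the existence of a phase cell mask is prescribed by the
assay — and its accuracy depends on the cell footprint being large relative
to the variance window; the test fixture uses 18 µm cells with a 10 px
window and recovers a known 33% coverage within ±0.05.

## Kinetics

Per (well, timepoint) the metric value is the arithmetic mean over that
well's replicate images; wells are then the unit of replication, and group
summaries report mean ± SEM across wells.

* **Slope.** Vendor software reports a per-curve "slope" index whose formula
  and units are not public; matching its absolute values is explicitly not
  attempted. The replacement defined (and documented) here: divide the
  series by its maximum, find the first sample reaching 0.9 of the maximum,
  and take the OLS slope of normalised value against time from the start
  through that sample, in fraction-of-max·min⁻¹. Zero-max or
  single-point-window series have slope 0 by convention. The definition is
  scale-invariant and halves under time dilation by 2.
* **AUC.** Trapezoidal rule over the full series.
* **Normalisation.** `percent_of_control = 100·mean(treated)/mean(vehicle)`
  on endpoint values; the endpoint defaults to the final timepoint
  (configurable). Vehicle mean ≤ 0 is an error, a vehicle group against
  itself is exactly 100.
* **Phases.** After a 3-point moving average: peaks are interior local
  maxima with prominence ≥ 0.2 of the smoothed maximum (boundary samples
  are not peaks); the plateau time is the first timepoint followed by ≥ 3
  consecutive intervals whose absolute discrete derivative stays below
  0.02·max per interval. The prominence/epsilon/run-length defaults are
  package choices — the behaviours being distinguished (biphasic uptake
  with peaks near 4 h and 24 h versus a plateau within a few hours) are
  qualitative.

## Simulator

The simulator provides ground truth for every pipeline stage; it is a test
harness, not a biological model. Mechanism: cells are placed uniformly at
random with minimum centre separation of one cell radius (packing error
after 1000 failed attempts per cell); each cell accrues engulfment events as
a homogeneous Poisson process with rate
λ = rate_modifier · λ₀ · c/(c + K), capped at `max_events_per_cell`;
each event's fluorescence onset lags engulfment by an exponential time
(mean `acid_lag_mean_min`) — the pH-switch property of the dye; visible
events render as isotropic Gaussian spots (σ 3 px, peak 10 corrected units)
at a uniform position inside their cell's footprint, over a quadratic
vignette (scaled to `background_amplitude`) plus Gaussian sensor noise,
clipped at zero. Phase frames are a constant background plus static
smoothed speckle confined to cell footprints. No photobleaching by default;
an optional exponential decay half-life exists to emulate non-monotone
long-term kinetics. `frame_times_min` can restrict rendering to selected
timepoints (e.g. endpoint-only) when intermediate frames are not needed.

Defaults (2 µm pixels, 192² px field, 40 cells of 12 µm radius, λ₀ =
0.05 min⁻¹, K = 100 µg/ml at a 200 µg/ml meal, 15 min mean acidification
lag, imaging every 10 min for 1 h, two images per well) approximate one
field of a 96-well assay at moderate confluence with a dose near
half-saturation. Randomness: one root seed; per-image streams derive from
`SeedSequence([root, crc32(well_id), image_index])`, so adding wells never
perturbs existing wells and identical seeds give bit-identical output.

What the simulator does *not* emulate: optics (no PSF beyond the Gaussian
spot), cell motility and division, multi-stage phagosome maturation,
spectral bleed-through, or focus drift. Passing tests therefore demonstrate
the correctness of the measurement chain, not robustness to those real-data
effects.

## Validation scenarios and problem sizes

Frozen scenarios (`phagoquant.scenarios`) encode the emulated experimental
designs at desk scale:

* **Sparse-event design** for rate recovery and dose titration: 448² px
  (~0.9 × 0.9 mm) at 2 µm/px, 150 cells of 20 µm radius, λ₀ =
  0.0125 min⁻¹ (≈ 0.75 expected engulfments/cell/h at the reference dose),
  endpoint frame only. The low rate keeps multiple engulfments per cell
  rare, because an object counter saturates once phagosomes crowd a cell —
  the worked example in the README shows this saturation deliberately.
  Under this design the endpoint count percent-of-control for a 0.3× rate
  condition recovers ≈ 30% and the integrated-intensity fold change for a
  2× condition ≈ 2 (intensity is additive under clumping, counts are not,
  which is why the enhancement scenario uses intensity).
* **Isolated-spot wells** for exact count recovery: 8 cells, ≤ 1 event
  each; a candidate well is re-simulated from the next derived sub-seed
  until all spots visible at 60 min are pairwise ≥ 4σ apart and ≥ 12 px
  from the border — the scenario *is* "well-separated spots", so rejection
  is part of its definition and deterministic given the seed.
* **Touching pairs** for declumping: two σ = 3 px Gaussians 8 px apart
  (2.67σ — merged by the threshold but bimodal), random position and
  orientation, over vignette and noise.

Test and acceptance problem sizes (200 oracle grids ≤ 64², 50 sparse wells,
100 clumps, 20 seeds per simulated arm, 5 dose levels) were chosen so the
whole suite completes in about a minute while keeping Monte-Carlo standard
errors several times smaller than the asserted margins.

## Numerical choices and degenerate inputs

Inclusive threshold and strict area cutoff as above; morphology borders
reflect; watershed ties resolve by scikit-image's deterministic flooding
order; label order is raster-deterministic; CSV output uses a fixed column
order and `%.10g` floats so identical inputs give byte-identical files.
Degenerate cases: constant images top-hat to zero and yield zero confluence
with a warning; empty masks produce empty (header-only) object tables;
zero-maximum series have slope 0 and no plateau; series shorter than 3 / 2 /
5 points are errors for slope / AUC / phase detection respectively.

## Known limitations

Object counts saturate at high per-cell uptake (use integrated intensity
there); the confluence mask inflates coverage of cells small relative to
its variance window; the edge split cannot separate blobs closer than
roughly 2σ (no bimodal valley exists); absolute values of the vendor slope
index are not reproduced, only its role as a relative rate readout.
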