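# Methods

`neurocult` quantifies astrocyte–neuron co-culture experiments from
fluorescence microscopy: live/dead viability and live-cell density from
stained nuclei, total neurite length from a neurite stain, spontaneous
spiking frequency from calcium-indicator movies, and replicate-aware
nonparametric comparisons between a co-culture condition and a mono-culture
control across seeding densities. Because the kind of dataset it targets is
rarely deposited, the package ships a synthetic-data generator that emits
the same experiment structure with exactly known ground truth; every
analysis stage is validated end-to-end against that truth.

## Experiment model

An experiment is a grid of conditions (co-culture vs control) × seeding
densities (default 1,000–50,000 cells/cm², six levels) × biological
replicates (independent cell preparations, default 2) × technical
replicates (wells within a preparation, default 5). Viability and neurites
are imaged at three randomized positions ("fields") per well; activity is
recorded as 2-minute movies at 32 Hz from three positions per well.
Technical replicates are the statistical unit; raw values are pooled across
biological replicates for testing, while fold changes are computed within
each biological replicate (each sample divided by the mean of that
replicate's control samples at the same density), which cancels
between-preparation variability.

## Synthetic data generator

The generator emulates the data structure, not the optics:

* **Viability fields.** Nuclei are isotropic Gaussian spots (σ = 3 px) on a
  flat background (100 counts) with additive Gaussian noise (σ = 2 counts),
  in a 512 × 512 px field at 1.3 µm/px (≈ 0.0044 cm²; the source protocol
  does not state a field size, so this is a declared assumption chosen to
  put ~4–220 cells in a field across the density range). Spot peak height
  is `contrast × noise_sd` (default contrast 10). Cells are placed by dart
  throwing with a 12 px minimum spacing; per-field cell numbers are Poisson
  around density × area. A configurable fraction can instead be placed as
  *touching pairs* (center distance 1.2–2.0 effective nucleus radii) to
  exercise declumping. Dead cells — exactly `round(n × dead_fraction)` —
  appear in the dead-stain channel, the rest in the live-stain channel; the
  live channel is generated for parity but never counted.
* **Dose–response defaults.** Co-culture viability rises from 0.70 at
  1,000 cells/cm² to a plateau of ~0.91 from 10,000 up; the control sits
  lower (0.69 at 10,000) and climbs only mildly. These curves are the
  generator's emulation of the published qualitative dose–response, not
  reproduced data.
* **Neurite fields.** Each cell grows 2–4 random-walk branches (4 px steps,
  0.25 rad heading jitter, reflecting at the borders); per-cell total
  length is Gamma-distributed (shape 4) around a condition-dependent mean
  (180 µm co-culture, 150 µm control). Vertices are snapped to the pixel
  grid *before* the analytic truth length is computed, so truth describes
  exactly the polyline that is rasterized (anti-aliased, max-composited).
  Somata appear only in the nuclei channel.
* **Calcium movies.** Cells are disks (r = 4 px) whose ΔF/F follows a
  homogeneous Poisson spike train (independent across cells; synchrony is
  deliberately not modeled — the pipeline measures frequency, not
  correlation) convolved with a difference-of-exponentials transient
  (τ_rise = 0.18 s, τ_decay = 0.55 s, peak amplitude 0.2 ΔF/F — a generic
  slow-indicator transient; all configurable since indicator kinetics vary).
  Per-pixel Gaussian noise has σ = 0.04 ΔF/F; optional linear or
  exponential photobleaching is off by default.

What the generator does **not** emulate: optical blur beyond the Gaussian
spot model, uneven illumination, autofluorescent debris, cell morphology
variation, overlapping neurites from dense mats, neuropil contamination,
or movement. Passing recovery tests therefore demonstrates the pipeline's
correctness and internal consistency on idealized images, not its
robustness to every real-world artifact; threshold multipliers and area
bounds are exposed precisely because real data need retuning.

## Viability counting

"Semi-automatic thresholding" is operationalized as a single user-chosen
multiplier resolved per image against robust background statistics:
`threshold = value × (median + k·MAD)` with k = 6 by default (≈ 4 noise SDs
above background for Gaussian noise). The median and MAD are background
estimates because objects occupy a small pixel fraction. Binarized images
are labelled with 8-connectivity; components below `min_object_area` (5 px)
are discarded as noise; components above `max_object_area` (75 px,
≈ 1.5 × the rendered single-nucleus area) are split by seeded watershed.
Watershed markers are local maxima of the lightly smoothed (σ = 0.6 px)
*intensity* inside the component — round stains give one intensity peak per
cell even when footprints merge, whereas distance-transform maxima fail on
strongly overlapping round objects (their union is convex). Two equal
Gaussian spots are unimodal below ~2σ separation, so pairs closer than that
are unresolvable in principle and set the method's residual undercount.

Well summaries sum counts over the well's fields before ratios:
`viability = (total − dead)/total`, with the summed dead count clamped to
the summed total (the two channels are counted independently and can
disagree on pathological input); `live density = live / summed field area`.
A well with zero counted cells has undefined (NaN) viability. The live
channel is never counted.

## Neurite length

The neurite channel is binarized (threshold resolved once on a designated
reference image per condition and reused verbatim for the whole condition),
thinned to 1-px centerlines by morphological skeletonization, and measured
with a diagonal-weighted step metric: 1 px per 4-adjacent pair, √2 px per
diagonal pair, with diagonal steps skipped when both legs of the
right-angle shortcut are present (so corners are not double counted). This
metric's worst-case bias on a straight digital segment is +8.2% at 22.5°,
below the 9% bound asserted in tests. Optional soma exclusion removes
skeleton pixels within a configurable radius of detected nuclei (off by
default, since whether somata contribute to a "neurite length" readout is a
reporting choice). Per well, lengths and cell counts are summed over fields;
fold changes are reported both for total length and for length per cell,
because normalizing by cell count before fold change is itself a reporting
choice.

## Calcium activity

A movie is reduced to a per-pixel temporal-activity summary — by default
the 95th-minus-5th percentile range over time — so that only cells whose
fluorescence actually moves are visible; "cells detected" therefore means
*active* cells, a documented semantic choice (a cell firing once or twice
in a recording has too small a duty cycle to clear the 5th/95th percentiles
and is invisible). Segmentation of the summary image uses the same
threshold/labeling/declumping contract as nucleus counting. Each ROI's
trace is the footprint-mean intensity; ΔF/F uses the 10th-percentile
baseline.

Events are detected with a continuous wavelet transform (Mexican-hat
mother wavelet, 8 scales geometric over 0.05–0.5 s — spanning the
transient's rise-to-peak width at 32 Hz). The per-scale noise floor is
`MAD(coefficients)/0.6745`; a candidate region must exceed
`k_noise = 4.25 ×` that floor at ≥ 3 contiguous scales for ≥ 0.15 s. The
duration requirement exploits the shape difference between transients
(elevated for hundreds of ms at these scales) and noise excursions (a few
frames), and is what pushes the false-event rate on pure-noise traces
below 1/2,000 traces while keeping event recall above 0.9 at peak-SNR 5.
Because the coefficient maximum of a symmetric wavelet sits near the
transient *peak* — roughly 0.3–0.5 s after the underlying event for slow
indicators — the reported event frame is refined to the steepest-rise
point of the smoothed trace within two wavelet widths before the maximum,
anchoring events at the transient onset (measured residual offset:
+0.07 ± 0.15 s). Candidates closer than the 0.25 s refractory interval are
merged keeping the larger coefficient. All constants live in
`WaveletSpec`. Well-level frequencies pool events and detected-cell counts
across the well's positions before the ratio (summed, not averaged per
position).

## Statistics

The group comparison is the one-sided Mann-Whitney U test. For
n₁·n₂ ≤ 100 the p-value is exact: all C(n₁+n₂, n₁) label assignments of
the pooled sample are enumerated and p is the fraction with a U at least
as extreme as observed — ties are handled automatically because midranks
of the pooled sample are fixed under permutation. Larger samples use the
normal approximation with tie-corrected variance and a 0.5 continuity
correction. The exact path is verified in tests against an independent
brute-force enumeration and against `scipy.stats.mannwhitneyu` on
tie-free data. Because the exact null distribution is discrete, the
achieved level is below nominal; e.g. for 4 vs 5 samples the largest
attainable one-sided level under 0.05 is 0.0317.

Summaries follow the plotting conventions of the emulated study: quartiles
by linear interpolation between order statistics (the convention changes
outlier sets, hence declared); outliers beyond 1.5 IQR from the quartiles
excluded in a *single pass* (fences are not recomputed after exclusion);
whiskers at the min/max of non-outlier values, clamped to the box edges on
degenerate samples; mean ± SEM (n−1 denominator); stars at p < 0.05 (\*),
< 0.005 (\*\*), < 0.0005 (\*\*\*), < 0.00005 (\*\*\*\*), strict
inequalities. No multiple-testing correction is applied, matching the
emulated analysis.

## Pipeline

`run_all` executes generate → viability → neurite → activity → stats in
dependency order, records every output with a SHA-256 checksum in a JSON
manifest together with the config snapshot and seed, and skips stages
whose inputs are checksum-identical to a previous run. All randomness
flows from a single integer seed; identical seeds give bit-identical
images, truth tables and result CSVs. The activity stage is off in default
experiment generation because calcium stacks dominate disk and runtime
(one 2-minute 96×96 movie is ~70 MB); analyses in the test suite use
reduced movie counts and durations for the same reason, stated per test.

## Problem sizes used in validation

Recovery and calibration runs use: 200 + 100 nuclei fields (clean /
touching-pair) of 50 cells; one full 6 × 2 × 2 × 5 experiment with 3
fields/well (360 fields); 50 arbor images of 10 cells at 256×256; 500
two-minute traces at 32 Hz for recall/precision plus 100 noise-only
traces; 100 + 2,000 Mann-Whitney cases for oracle agreement and null
calibration; and 100 simulated experiments for end-to-end power.

## Known limitations

* Counting accuracy is specified for spot-like nuclei with peak SNR ≥ 5;
  clumps of ≥ 3 mutually touching cells and pairs below ~2σ separation
  undercount.
* The skeleton metric inherits the ±9% digital-straight-line bias; lengths
  of strongly curved or crossing neurites can deviate further.
* ΔF/F with a percentile baseline assumes sparse activity; a cell active
  more than ~50% of the time would have an inflated baseline.
* Event detection is calibrated for isolated transients; burst doublets
  within the refractory interval merge into single events by design.
* The generator's independence assumptions (no synchrony, no spatial
  intensity structure) make recovered frequencies cleaner than real
  recordings; real data require re-choosing the threshold multipliers.
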