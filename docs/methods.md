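# Methods

`pushscope` quantifies how a confined, migrating immune cell coordinates its
central actin pool with its leading edge. The package re-implements, as
tested and reusable operations, the bespoke image-quantification procedures
of that assay family: pushing-force microscopy from embedded beads,
per-compartment contribution classification, 2D cell morphometry, lagged
cross-correlation of per-cell time series, constriction density profiles and
deformation/actin maxima proximity. Because no imaging data is publicly
deposited for these assays, every stage is validated against a synthetic
scene generator with exact ground truth; this note records what each stage
assumes, the parameters that matter, and the numerical choices made where
the procedure descriptions left the design open.

## Pushing-force microscopy (bead displacement)

**Model.** Sub-resolution fluorescent beads are embedded in an elastic gel
over the cells. A cell passing beneath a bead lifts the gel and the bead
with it; the bead's vertical (Z) excursion from its resting depth is the
readout of pushing force. The analysis is purely kinematic — no elastic
modulus is fitted, and displacements are reported in micrometers.

**Procedure.**

1. *Detection* (`beads.detect_beads`): candidate beads are connected
   components of the Otsu-thresholded maximum-intensity projection over Z
   and time. The projection is Gaussian-smoothed (`smooth_sigma_px`,
   default 1) first; a max projection over ~10^3 samples per pixel lifts the
   background toward its extreme-value tail, and without smoothing Otsu's
   threshold is bistable at realistic noise. Components are rejected as
   aggregates (area above `max_area_px`), debris (below `min_area_px`),
   border-clipped (within the analysis half-width of the edge) or
   nonstationary (per-frame intensity-weighted centroid deviating more than
   `stationarity_max_shift_px`, default 2, from its time mean; the centroid
   is computed after subtracting the local median so background noise in the
   bounding box does not dilute it).
2. *Kymograph* (`beads.extract_kymograph`): mean intensity over a fixed
   5 × 5 px XY window around the bead, per (z, t). The mean (not the sum)
   keeps units independent of the window size. A window that would leave the
   image is an error, never silently clipped.
3. *Edge tracking* (`beads.track_edge`): one global Otsu threshold on the
   whole kymograph (a per-frame threshold jitters with noise). Per frame the
   crossing is located by walking outward from the profile peak toward the
   side away from the coverslip (the cell pushes beads deeper into the gel)
   and interpolating linearly between the bracketing samples. Walking from
   the peak makes the edge immune to isolated noise excursions beyond the
   bead. The kymograph is Gaussian-smoothed before thresholding
   (`smooth_sigma_zt`, default 1.5 z-steps × 1.5 frames — about half the
   bead's axial extent and one sampling interval); with a 0.1 µm z-step,
   discretization and single-voxel noise dominate the error budget
   otherwise. Degenerate two-level kymographs use the midpoint threshold
   (Otsu's criterion is flat over the gap), which also fixes the
   interpolation contract: a step edge exactly between samples reads
   k + 0.5 steps.
4. *Baseline and displacement*: displacement is the tracked edge minus a
   no-cell baseline. The preferred baseline is the mean edge over frames the
   contribution classifier labels `none`; without labels, the first/last
   valid frames are used. The maximum displacement of a trace is the largest
   absolute displacement over valid frames.

## Contribution classification

Per bead, the actin-reporter and DNA-stain channels are summed over Z and a
20 × 20 px window per frame. One-dimensional K-means (10 restarts, fixed
seed) on the actin trace separates intensity regimes; clusters map to labels
by ascending mean — `none` < `cytoplasm` < `central_actin` with k = 3, or
`none` < `cytoplasm` with k = 2 for cells that lack a central pool.
Clustering is per bead (absolute intensities vary with depth and labeling);
a pooled mode exists for uniformly imaged cohorts. Frames in the upper
cluster of a two-way split of the nucleus trace are relabeled `nucleus`,
overriding the actin label — actin is present beneath the nucleus, and
nuclear passage is a distinct mechanical regime. The override requires the
two nucleus clusters to be separated by more than `nucleus_min_separation`
(default 4) pooled within-cluster standard deviations, so a flat nucleus
trace never produces nucleus labels. Runs shorter than `min_dwell_frames`
(default 2) are absorbed into their neighbor: at 30 s sampling, compartment
passages last minutes and single-frame flicker is noise.

Per-region summaries report the mean edge position over each label's valid
frames minus the `none` baseline; the `none` region is therefore 0 by
construction, and regions with no frames are absent rather than zero.

## Cell morphometry

Segmentation is a threshold stand-in for a trained pixel classifier:
largest connected component of the Otsu-thresholded, smoothed actin frame
for the cell; a second, higher threshold (Otsu of in-cell intensities,
floored at the 75th in-cell percentile) eroded away from a 2 px boundary rim
for the central pool; Otsu on the DNA channel for the nucleus. Externally
produced masks bypass all of this unchanged.

Tracking is greedy nearest-centroid linking with a gate (`max_step_px`,
default 20 px/frame). Tracking here only isolates well-behaved cells, so a
globally optimal assignment is unnecessary; frames where two masks touch
terminate both tracks, and tracks of 10 frames or fewer are discarded
(strictly: length 11 survives). Speed is the center-of-mass step length per
frame interval, in µm/min. Protrusion decomposition is the exact set
difference of consecutive masks (gained = new area, lost = retracted area);
the area-conservation identity `area(t+1) − area(t) = gained − lost` holds
exactly. All intensities are integrated and background-corrected (median
outside the cell masks by default), making every reported ratio invariant to
camera gain and uniform offset; negative corrected totals are clipped to
zero with a warning. Orientation calls project the MTOC-to-nucleus vector
onto the polarization axis (by default the centroid velocity over a ±2-frame
window); |projection| under one pixel is a tie, reported `nucleus_first`
with a flag. Retraction events are pooled by dividing each region's series
by its value at the event onset and aligning onsets at lag 0; lags covered
by fewer than two events are flagged.

## Cross-correlation and significance

`cross_correlate(x, y)` reports, for every lag ℓ in −L..L, the Pearson
correlation of the overlapping segments x_t and y_{t+ℓ}, each mean-centered
and normalized on the overlap itself so r is a true correlation at every lag
(short tracks make edge effects material). Positive lag means y follows x.
The peak is the largest |r|, ties broken toward lag 0. An optional moving-
median detrend (window 2L + 1) is off by default. Default L = 10 frames
(5 min at 30 s sampling).

Significance of the peak uses the statistic max_ℓ |r| against surrogate
copies of y with randomized Fourier phases (periodogram — hence
autocorrelation — preserved, alignment destroyed), with the add-one
estimator p = (1 + #{null ≥ observed})/(B + 1). A circular-shift null
restricted to offsets beyond L is available for comparison but is
structurally anti-conservative on short series: the shifted lag windows
overlap each other but can never overlap the observed window, so the
effective number of exchangeable draws is about n/(2L + 1) regardless of B.
The test suite measures the phase null's type-I error at α = 0.05 as ~0.03–
0.05 on both white-noise and autocorrelated series; an i.i.d. shuffle would
be anti-conservative for smooth series and is deliberately not offered.

## Constriction profiles

The channel lumen is segmented from brightfield (threshold + largest
component + hole filling) or supplied as a mask. The actin signal is
averaged vertically over mask pixels per column — a mean, so channel height
does not enter — giving a longitudinal density profile per frame; the final
profile is the per-column maximum over time, and the reported ratio is the
profile peak inside the constriction interval (half-open pixel interval,
0-based) over the peak outside. Columns with no mask pixels are absent, not
zero. Per-column background (median over cell-free frames, or the temporal
minimum when cell presence is unknown) is subtracted by default; the ratio
is gain-invariant either way.

## Maxima proximity

Local maxima of a deformation-magnitude field (computed upstream by PIV;
accepted as input) and of an actin field are detected independently: strict
maxima of a circular neighborhood (`radius_px`) exceeding a prominence floor
above the field median. The default prominence is max(3 scaled MADs,
5% of the dynamic range) — MAD alone collapses on fields that are mostly
flat background. Ties within one neighborhood keep the lexicographically
smallest coordinate. Distances are directed (each deformation maximum to its
nearest actin maximum, per Z-slice and timepoint, via a KD-tree); slices
with no actin maxima are flagged absent rather than infinite.

## Synthetic scenes and what they do (not) show

The generators are geometric test harnesses, not mechanical or optical
models. Determinism is contractual: identical parameters and seed give
byte-identical output (one seeded stream per scene, child streams per
channel).

*Bead scenes* render beads as 3D Gaussians (σ = 0.45 µm, FWHM ≈ 1.06 µm —
the Gaussian proxy for a 1 µm sphere under a confocal PSF) at 0.1 µm
z-steps, one frame per 30 s, 40 frames (a ~20 min acquisition). A disk-
shaped cell (radius 10 µm) with a bright central pool (radius 4 µm, 1 µm
behind the center) and a trailing nucleus (radius 2 µm, 8 µm behind)
traverses the field at 0.05 µm/s; beads sit on its path in two staggered
rows inside the pool's swath, so each experiences the full passage sequence
and remains resolvable from its neighbors. The true bead Z-center follows
baseline + amplitude × envelope, where the envelope is 1 inside the pool and
nucleus footprints with a raised-cosine shoulder (4 µm; gel deformation
spreads beyond the indenting structure) and a small cytoplasm term (fraction
0.15, 1.5 µm shoulder; the thin lamella deforms the gel locally and weakly).
A directly overrun bead therefore reaches the full amplitude exactly.
Default amplitude 0.8 µm; default noise gives a peak-signal-to-noise ratio
of 5 (peak 100, Gaussian σ 20; optional Poisson). The displacement envelope
is a smooth bump, not a solution of an elastic problem — recovery tests
validate the tracking, not gel mechanics.

*Migration movies* couple a latent protrusion series and a latent pool
series: pool = c·protrusion delayed by the planted lag plus an independent
smooth residual scaled so |coupling| = 1 is exact. The latents modulate the
lamellipodial band and central pool intensities of a moving disk cell.
Passing tests show the pipeline recovers planted couplings from rendered
images; they do not show that real cells behave like disks with sinusoidally
modulated compartments.

*Constriction movies* sweep a cell segment through a channel whose actin
level inside the constriction interval is exactly `enrichment_factor` times
the outside plateau. *Field pairs* plant Gaussian peaks on the integer pixel
grid with integer-vector pair offsets (norm within half a pixel of the
nominal offset), so the recorded truth is exactly the argmax of the rendered
field.

## Problem sizes

The validation suite and the acceptance script run at the generator default
sizes: one 40 × 28 × 96 × 240 bead scene with 20 beads per check, cohorts of
50 latent series for coupling signs, 500 white-noise pairs with 1000
surrogates each for the type-I calibration, and 40-frame constriction
movies. These sizes give binomial uncertainties comfortably inside the
stated tolerance bands while keeping a full run in tens of seconds.

## Known limitations

- Segmentation is threshold-based; cells with weak or textured reporter
  expression need externally supplied masks (supported everywhere).
- The nearest-centroid linker does not resolve crossings; it is meant to
  isolate non-interacting cells, matching how tracking is used upstream.
- The bead-edge tracker assumes one bead per analysis window; fused pairs
  are rejected at detection rather than deblended.
- The phase-surrogate null assumes the series is reasonably stationary;
  strongly drifting series should be detrended first (flag provided).
- PIV and pixel-classifier training are out of scope; deformation fields
  and classifier masks are accepted as inputs.
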