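# Methods notes

This note documents the models behind each recruitkit module, the defaults
and why they were chosen, the numerical decisions that matter, and what the
synthetic-data tests do and do not demonstrate about real data.

## GUV recruitment quantification (`guv_quant`)

### Model

A GUV imaged in a confocal section appears as a ring whose cross-section we
model as Gaussian with width σ (px). Segmentation follows the local-contrast
construction: the membrane channel is transformed to
`C(p) = max − min` over a disk of radius `window_radius`, and the ring mask
is `C ≥ T` with `T` the Otsu threshold of `C`. The readout is the mean
protein intensity over the ring pixels, minus the average of two background
estimates: the vesicle lumen (filled region minus ring, eroded by
`margin_px`) and the frame exterior (complement of all filled regions,
dilated by `margin_px`). Averaging an interior and an exterior estimate makes
the readout exactly invariant to additive offsets of the protein channel and
keeps it linear under intensity scaling — both are property-tested.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `window_radius` | 4 | px | ≈ membrane σ; see operating-point analysis below |
| `min_area_px` | 50 | px | rejects noise specks; below any plausible ring |
| `margin_px` | 3 | px | keeps background estimates off the ridge tails |
| `drop_border` | true | — | truncated rings bias ring means |
| `max_link_px` | 10 | px | GUVs drift ≪ their radius per frame |
| `min_track_fraction` | 0.5 | — | discards transient spurious detections |

### Operating point: why `window_radius ≈ σ`

The contrast profile of a Gaussian ring has a plateau of half-width ≈ the
window radius `w`, decaying with the membrane's own σ beyond it, so the
thresholded band has half-width ≈ `w + σ·sqrt(2·ln(1/τ))` for a relative
threshold τ. The ground-truth band used by the simulator is |d−r| ≤ 2σ
(≥95% of the Gaussian cross-section mass). A characterization scan over
σ × w showed that `w ≈ σ` maximizes the overlap between segmented and truth
bands (Jaccard ≈ 0.82–0.85 at σ = 3.5, w = 3–4) while keeping full ridge
contrast; larger windows dilate the band and dilute the ring mean. With the
defaults the segmented band is still ≈ ±2.4σ, so the segmented-pixel mean
sits systematically ≈13–15% *below* the ±2σ-band ground truth. This bias is
intrinsic to thresholding a Gaussian profile — any band wider than the truth
band lowers the mean — and is stable across frames, so kinetic shapes and
condition comparisons are unaffected. Accuracy statements are therefore made
in amplitude-normalized terms: under the 10-vesicle recovery conditions
(radius 20 px, σ 3.5 px, exponential rise k = 0.1/min, 8 frames over 35 min,
noise 5% of amplitude) the aggregate-trajectory RMSE is ≈6% of the protein
amplitude (asserted ≤10%).

### Numerical choices

* Otsu threshold: 256 fixed-width bins over the value range; the objective
  `ω₀ω₁(μ₀−μ₁)²` is scanned exhaustively; ties resolve to the lowest cut.
  Because exact ties occur whenever empty bins separate two modes, the
  argmax accepts any cut within 1e−10 relative of the maximum and takes the
  lowest — a tie-break that is stable under floating-point summation order
  (verified against an exact rational-arithmetic oracle).
* Borders in `local_contrast` are handled by edge replication; the output is
  non-negative everywhere.
* A blank (constant) frame yields an empty segmentation, not an exception;
  an empty lumen after erosion falls back to the exterior-only background
  with a warning.
* Tracking uses a globally optimal (Hungarian) assignment gated at
  `max_link_px`; sample SD across GUVs uses ddof = 1 (GUVs are the
  replication unit).
* No photobleaching correction is applied; trajectories are reported raw.

## Bead quantification (`bead_quant`)

The threshold is `(mean_inside + mean_outside)/2`, where "outside" is a
10-px annulus around the bead (excluding other beads) so the reference is
local and robust to illumination gradients. The reported value is the mean
of inside pixels at or above the threshold — i.e. sub-threshold inside
pixels are excluded, which reads the threshold as a mask-refinement step.
When the inside mean does not exceed the outside mean the measurement is
flagged degenerate and the plain inside mean is reported. Contour pixels
count as inside. Aggregation is mean ± sample SD (ddof 1) across beads.

## Differential HDX (`hdx_diff`)

* %D normalization between the unexchanged (H₂O) control and the
  maximally-labeled control (longest exchange time, 60000 s by convention)
  cancels any uniform back-exchange retention; out-of-range values are
  flagged, never clamped, so difference arithmetic stays exact.
* The maximally-labeled control is taken per condition; the unexchanged
  control is shared across conditions.
* Sign convention: `Δ%D = condition − reference`; protection is negative.
  The classifier is symmetric under a flip of this convention (tested).
* SD of a difference is propagated in quadrature — replicates are not
  paired across conditions in the protocol.
* Classification uses a fixed ±10-point effect-size threshold at the 60 s
  timepoint by default (other timepoints are reported but only classified
  on request). No multiple-testing correction applies because no p-values
  are computed.
* Region merging treats residue spans as 1-based inclusive; spans merge when
  they overlap or abut within `gap_tolerance` (default 0, i.e. only directly
  abutting spans merge). Output regions are sorted and disjoint.
* Masses: deuteron mass shift 1.00628 Da; proton mass 1.00728 Da for m/z
  conversion.

## Contour statistics (`cc_trace`)

* `path_statistics` never smooths or resamples user-supplied paths: contour
  length is the raw chord sum, matching how interactive tracing tools report
  track lengths.
* `predicted_cc_span` uses the canonical coiled-coil axial rise of
  1.485 Å/residue.
* `domain_residue_count` uses the boundary-difference convention
  (`end − start`) under which the 790–1500 coiled-coil domain comprises 710
  residues — note this differs from the inclusive peptide-span count used in
  the HDX module.
* `trace_centerline` binarizes at the Otsu threshold, skeletonizes, and
  takes the minimum-cost 8-connected path (Euclidean step costs) between the
  skeleton pixels nearest the requested endpoints. Two corrections remove
  known digital biases: (1) the path is anchored at the requested endpoints,
  because skeletonization erodes the tube caps by roughly the tube radius;
  (2) the pixel chain is smoothed with a 5-point centered moving average
  (ends fixed, window configurable, 1 disables), because a raw 8-connected
  chain overestimates the length of a smooth curve by up to ~8%
  (≈5% on average over orientations). With both corrections the traced
  length of a straight tube is exact and of a semicircular tube is within
  0.1% of the analytic arc length; the tests assert 2% and 3% respectively.
* Histograms default to 10 nm bins from zero.

## Synthetic data (`synthetic_data`)

What the generators emulate — and do not:

* **GUV time-lapse**: Gaussian-cross-section rings with recruitment kinetics
  R(t) ∈ {constant, exponential rise 1−exp(−kt), logistic}, lumen/exterior
  backgrounds, additive Gaussian noise. Defaults (radius 20 px, σ 3.5 px at
  0.1 µm/px, amplitudes 100, backgrounds 2/6, noise 5) describe a ~4 µm GUV
  with a PSF-broadened membrane cross-section and 5% noise. Not modeled:
  optics/PSF, z-sectioning, photobleaching, membrane fluctuations, protein
  clustering into domains. Ground truth per vesicle is the noiseless
  protein-channel mean over the true |d−r| ≤ 2σ band minus the average
  background.
* **HDX**: per-residue exponential exchange, uniform back-exchange retention
  (default 0.7), replicate Gaussian mass noise, timepoints 6/60/600/60000 s
  with the 60000 s sample defined as fully labeled. Not modeled: EX1
  kinetics, site-specific retention, peptide overlap deconvolution, spectral
  interference.
* **Isotope envelopes**: binomial deuteration weights (normalized before
  convolution) under Gaussian peaks; intended for testing centroid
  operations, not for profile-mode spectrum simulation.
* **Filaments**: tubes of Gaussian cross-section along a line, circular arc,
  or sinusoid, each with a closed-form arc length (the sinusoid via the
  incomplete elliptic integral of the second kind). Not modeled: stain
  granularity, overlapping particles, branching.

All generators are bit-deterministic under their seed. Passing tests on
these simulations demonstrates correctness of the estimators under the
stated noise model; they do not certify performance on real micrographs or
spectra, where segmentation and identification errors dominate.

## Problem sizes

The test suite and examples use desk-scale problems chosen to exercise every
code path with comfortable statistical margins: 10 vesicles × 8 frames at
160×400 px for kinetic recovery; 100 seeded replicate HDX experiments of 20
peptides × 2 conditions × 4 timepoints × 3 replicates for classification
recovery; 100 random instances per brute-force oracle comparison; 117
simulated arcs for ensemble statistics. The full suite runs in well under a
minute on one CPU.

## Known limitations

* The segmented-band bias (≈13–15% underestimate of the ±2σ-band ground
  truth) is inherent to Otsu-band segmentation of Gaussian rings; absolute
  ring intensities should be compared only within a fixed acquisition and
  analysis configuration.
* Vesicle tracking is nearest-centroid only; it is not designed for dense
  fields or fast drift.
* HDX analysis is peptide-level; no residue-level deconvolution of
  overlapping peptides is attempted.
* `trace_centerline` assumes a single unbranched ridge between the
  endpoints; spurs are tolerated (shortest path ignores them) but branches
  of comparable intensity can divert the path.
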