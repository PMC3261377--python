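# Methods

## Problem

Cine-MRI of the rodent heart acquires a stack of short-axis slices, each
resolved into 20–30 frames per cardiac cycle, and derives global
left-ventricular (LV) function from them: end-diastolic and end-systolic
blood-pool volumes (EDV, ESV), stroke volume (SV = EDV − ESV), ejection
fraction (EF = 100·SV/EDV) and LV mass (LVM). Scan time is proportional to
the number of phase-encode lines acquired per frame; omitting lines
accelerates the scan at the cost of aliasing. Compressed sensing (CS)
recovers images from sub-Nyquist data when (i) the image series is sparse
in some transform, (ii) the sampling is incoherent, and (iii) a nonlinear
reconstruction is used. This package implements that full loop — sampling
design, reconstruction, quantification — and validates it on a synthetic
beating-heart phantom with exactly known ground truth.

## Sparsifying transform

For a cine train {x_i}, i = 1…N, the temporal average

    A = (1/N) Σ_i x_i

captures the static anatomy; the differences s_i = x_i − A carry only the
dynamic content and are sparse. The transform is linear, exactly
invertible, and is applied in complex arithmetic (magnitudes are taken
only at the very end of post-processing). The ℓ1 norm of a complex image
is the sum of moduli.

## Sampling pattern design

Masks are binary k-t matrices (frames × phase-encode lines). Per frame,
`round(n_pe / R)` lines (round-half-to-even; non-integer R such as 2.5 is
allowed) are drawn without replacement with selection probability
proportional to a Gaussian centered on k-space (width σ, default n_pe/6 —
roughly all weight inside k-space with usable tails; the value is a free
parameter and configurable). The center line is always included: densely
sampled low spatial frequencies are critical for CS. A deterministic
repair pass then guarantees every line is measured at least once over the
cycle (each missing line displaces the currently most-oversampled line in
the first frame that holds it), which makes the composite average image
well defined.

Pattern quality is scored by the point-spread function (PSF) of each
frame's mask along the undersampled dimension: the inverse DFT of the
binary row, whose off-mainlobe maximum over mainlobe ratio
(sidelobe-to-peak) measures how coherent the aliasing is. The aggregate
score of a pattern is the *maximum* per-frame ratio — conservative, since
the worst frame bounds the artifact structure; scoring a joint k-t PSF
instead would be a reasonable alternative. Selection generates 200
candidates from a seeded stream and keeps the minimizer (ties to the
lowest index). Patterns round-trip losslessly through a scanner-style
text format (header plus one line of 0-based ascending indices per frame).

## Reconstruction

The solver addresses the Lagrangian ℓ1 problem

    min_x  μ‖T x‖₁ + ½‖R x − k‖₂²

with T the subtract-average transform, R the mask composed with the
unitary centered 2-D Fourier transform, and k the measured samples.
μ = 0.5 by default, in the acquisition's (arbitrary) intensity units; the
phantom's intensity scale is chosen so this default is meaningful (below).

Algorithm per slice:

1. **Average estimate.** Each phase-encode line is averaged over the
   frames that measured it (count-weighted composite k-space) and
   inverse-transformed. Exact for a static object under any pattern with
   full coverage.
2. **Proximal gradient on the differences.** With x_i = A + s_i and
   b_i = k_i − M_i F A, iterative soft-thresholding solves
   min_s μ‖s‖₁ + ½‖M F s − b‖₂² jointly over frames: a gradient step on
   the data term (step 1 is safe; mask∘unitary-Fourier has operator norm
   ≤ 1) followed by complex soft-thresholding of moduli by μ·step.
   Stopping: relative objective change < `tol` (default 1e−6) or
   `max_iters` (default 200; hitting it logs a warning and returns the
   best iterate, never raises).
3. **Data-consistency projection** (`final_dc`, default on): measured
   k-space locations are restored to the measured values, so the residual
   at acquired samples is exactly zero and a fully sampled acquisition
   reconstructs to the plain inverse FFT.
4. **Alternation** (`outer_loops`, default 3): A is re-estimated as the
   temporal average of the current reconstruction and steps 2–3 repeat.
   The one-shot composite average is biased for a moving object — each
   line sees a different subset of the cycle — and that bias pulls the
   unmeasured lines of every frame toward a blurred cycle, systematically
   inflating ESV and depressing EF. A few alternation passes measurably
   restore motion amplitude. The alternation is not a convergent
   fixed-point iteration (the average drifts slowly once the dynamic
   content is recovered), so a small fixed pass count is used rather than
   an outer tolerance; `outer_loops=1` gives the plain fixed-average
   scheme. For optimizer verification, `outer_loops=1, final_dc=False` is
   the pure Lagrangian mode whose objective can be compared against an
   independent reference minimizer.

### Intensity scale and μ

μ acts as an absolute threshold, so its effect is relative to the data
scale. The phantom uses blood 10, myocardium 6, background 0.5 (arbitrary
units) with complex k-space noise SD 0.1 per component (SNR ≈ 100 against
blood; the noise floor is visible against the dim background but does not
dominate). On this scale the default μ = 0.5 sits between the
aliasing/noise floor of the difference images and their true dynamic
amplitudes, which is the regime in which an ℓ1 penalty denoises without
erasing motion. CS recovery statements are inherently scale-relative: a
sparse scene whose dynamic amplitude is comparable to μ will be shrunk
toward the average regardless of sampling quality.

### Sampling density vs. sparsity structure

The center-weighted Gaussian density matches image-like signals whose
k-space energy is concentrated at low frequencies. For scenes sparse in
the *pixel* basis (e.g. a handful of time-varying pixels), theory favors
near-uniform random sampling; with the default σ = n_pe/6 the outer
k-space is so rarely sampled that point-sparse recovery saturates around
1.4% NRMSE however long the solver runs, while a wide density (σ ≈ n_pe)
takes the same solver below 1% NRMSE at R = 3. The sparse-recovery tests
therefore use a wide density; the cardiac pipeline keeps the
center-weighted default.

## Post-processing

Fixed order: reconstruction → symmetric k-space zero-filling (factor 2,
giving 50 × 50 μm² in-plane pixels at the 25.6-mm FOV / 256 matrix) →
radial Butterworth low-pass applied in k-space,
g(f) = 1/√(1 + (f/f_c)^(2·order)) with order 3 and cutoff 0.95 of the
Nyquist radius (mild apodization; gain 1 at DC, 1/√2 at the cutoff for
any order) → inverse Fourier transform → magnitude. Zero-filling
preserves the total image intensity (the padded k-space is scaled by
1/factor under the unitary convention). Magnitudes export to multi-page
16-bit TIFF with the scale factor recorded in the page description.

## Phantom

Per slice, a circular blood pool inside an annular myocardium on a static
background. Frame 0 is end-diastole; the endocardial radius follows a
raised cosine over the cycle with peak fractional reduction
`contraction_fraction` (default 0.35, giving EF ≈ 1 − (1 − 0.35)² ≈ 58%
for a cylinder stack — the physiological range for a healthy mouse). The
epicardial radius preserves annulus *area* (wall thickening without
in-plane myocardial volume change); LV mass is defined on the
end-diastolic frame with density 1.05 mg/μL. Radii taper linearly from
base to apex. Defaults: 8 slices × 1 mm, FOV 25.6 mm, matrix 256,
26 frames. Ground-truth volumes are voxel counts of the rasterized label
masks times voxel volume — not the analytic radii — so quantification of
noiseless data recovers them exactly; end-systole is the first frame of
minimal blood-pool volume.

What the phantom does *not* emulate: MR contrast mechanisms (T1/T2, flow
enhancement), through-plane motion, papillary muscles and trabeculation,
gating jitter, coil sensitivity profiles, or realistic anatomy. Passing
tests therefore demonstrate the correctness and internal consistency of
the sampling/reconstruction/quantification chain under controlled
conditions, not segmentation accuracy on real hearts.

## Quantification

Label masks (0 background, 1 myocardium, 2 blood) are quantified by voxel
counting; ED/ES frames default to maximal/minimal total blood-pool volume
(ties to the earliest frame), which is robust to reconstruction blur. A
threshold segmenter (two pooled Otsu thresholds; blood reduced to its
largest connected component per slice and frame) lets the phantom's
magnitude reconstructions be quantified automatically; it is adequate for
piecewise-constant phantom images and is explicitly not a validated
cardiac segmenter.

Agreement statistics: Bland–Altman bias = mean of paired differences
(method 2 − method 1), SD with n−1 denominator, limits = bias ± 2·SD.
Observer variability per pair = 100·(a − b)/((a + b)/2), reported as
mean ± SD; the sign convention makes swapping observers negate the
differences. Protocol comparison tables report mean ± SD per metric in
the fixed row order LVM, EDV, ESV, SV, EF.

## Validation experiment

`run_validation_experiment` reconstructs one phantom acquisition at each
configured R (default {1, 2, 2.5, 3, 4}), reusing one selected pattern
per R across slices (the scanner workflow: a stored pattern is chosen per
heart rate and acceleration). It reports per-R LV metrics, reconstruction
NRMSE against the noiseless phantom magnitudes, and Bland–Altman
agreement of per-slice ED/ES blood-pool volumes against the fully sampled
reference — a single phantom has no animal cohort, so slices provide the
pairing. Every random draw is traceable to a named seed in the run
manifest, and a repeat run is byte-identical in its numeric report.

The default validation scale used by the tests and the acceptance script
is matrix 128, 20 frames, 4 slices — the same physiology on a coarser
grid, sized so the full five-R experiment completes in about a minute on
one CPU. At that scale the package reproduces the method's headline
behavior: 3-fold undersampling changes EF by ≈ 2–3 percentage points and
EDV by ≈ 1–2%, while reconstruction NRMSE grows monotonically with R and
R = 4 degrades markedly — the basis for choosing R = 3 as the operating
point.

## Numerical conventions and edge cases

- All Fourier transforms are unitary and centered (DC at index n/2, even
  matrices); Parseval's identity is exact.
- Pattern indices are 0-based; R = 1 always yields an all-ones mask.
- `lines_per_frame` uses round-half-to-even; every frame gets the same
  count.
- Degenerate inputs raise `ValueError` naming the offending field or
  file line (empty series, radii out of order, coverage-unattainable
  patterns, never-measured lines, empty blood pool at ED, ESV > EDV).
- Solver non-convergence at `max_iters` is a logged warning, not an
  exception.

## Known limitations

- The alternation depth (3) trades EF fidelity against a slow drift of
  the average image; it is a fixed count, not a converged quantity.
- The Butterworth "modification" used by scanner-side implementations is
  not reproducible; the standard radial form is used with cutoff 0.95.
- The aggregate PSF score uses the per-frame maximum; a joint k-t PSF is
  a plausible alternative and untested.
- Quantification accuracy on real (non-piecewise-constant) data depends
  on the segmenter, which is out of scope here.
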