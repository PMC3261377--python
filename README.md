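# cscine

Compressed-sensing cine-MRI for small-animal cardiac imaging: k-t
undersampling pattern design, temporal-sparsity ℓ1 reconstruction, and
left-ventricular functional quantification, validated end-to-end on a
synthetic beating-heart phantom with exactly known ground truth.

## Who this is for

Preclinical MR groups (and anyone building dynamic-imaging CS pipelines)
who want to accelerate multi-frame cine acquisitions by undersampling the
phase-encode direction — without parallel-imaging hardware — and need to
know how far they can push the acceleration factor R before global
cardiac parameters (LVM, EDV, ESV, SV, EF) degrade.

## The method

A cine train {x_i}, i = 1…N, of a beating heart is sparse after
subtracting its temporal average A = (1/N)Σ x_i: the differences
s_i = x_i − A carry only the motion. Acquisition omits phase-encode
lines frame-by-frame according to a random, Gaussian-center-weighted
binary k-t mask, chosen as the best of 200 candidates by the
sidelobe-to-peak ratio of the mask's point-spread function (maximally
incoherent aliasing), with every line measured at least once per cycle.
Reconstruction solves the Lagrangian ℓ1 problem

    min_x  μ‖T x‖₁ + ½‖R x − k‖₂²,    μ = 0.5,

where T subtracts the average image and R is the mask composed with the
unitary Fourier transform, by iterative soft-thresholding on the
difference images with a final exact data-consistency projection, and a
few alternation passes refining A. Post-processing is 2× zero-filling, a
third-order radial Butterworth filter, Fourier transform and magnitude
export to multi-page TIFF. Volumes are quantified from segmentation label
masks by voxel counting; method agreement uses Bland–Altman statistics
(bias ± 2 SD limits) and percent observer variability.

See `docs/methods.md` for the model, algorithms, parameter defaults and
limitations.

## Worked example

`examples/05_validation_experiment.py` runs the full loop — phantom →
pattern → undersample → reconstruct → quantify — at matrix 128, 20 frames,
4 slices, R ∈ {1, 2, 2.5, 3, 4} (about a minute on one CPU):

```
# LV metrics per undersampling factor R
,R=1,R=2,R=2.5,R=3,R=4
LVM,31.584000,31.195500,30.628500,30.786000,30.009000
EDV,21.750000,21.550000,21.330000,21.430000,21.140000
ESV,9.760000,9.850000,9.900000,10.170000,10.280000
SV,11.990000,11.700000,11.430000,11.260000,10.860000
EF,55.126437,54.292343,53.586498,52.543164,51.371807

# Reconstruction NRMSE vs noiseless phantom [%]
R=1: 8.945908
R=2: 11.634181
R=2.5: 12.333104
R=3: 13.857823
R=4: 15.632689

ground-truth EF: 56.52 %
EF change at R=3 vs fully sampled: -2.58 percentage points
EDV change at R=3 vs fully sampled: -1.47 %
```

Reading this: the reconstruction error (NRMSE against the noiseless
phantom) grows monotonically with acceleration, but the functional
parameters measured from the reconstructions stay within a few percent of
the fully sampled values up to R = 3 — EF drops by 2.6 percentage points
and EDV by 1.5% — while R = 4 degrades further. That is the quantitative
basis for running 3-fold accelerated cine scans. The remaining offset
between the R = 1 row and the ground truth is the noise floor plus
segmentation discretization, shared by all protocols.

The other examples each demonstrate one capability: phantom ground truth
(`01`), pattern design and PSF scoring (`02`), CS reconstruction of one
slice (`03`), quantification and agreement statistics (`04`).

A thin CLI wraps the same functions:

```bash
cscine pattern --n-pe 256 --n-frames 26 --r 3 --out pattern_r3.txt
cscine phantom --out kspace.h5 --truth-out truth.json
cscine undersample --kspace kspace.h5 --pattern pattern_r3.txt --out und.h5
cscine recon --kspace und.h5 --out-prefix recon
cscine validate --out results/
```

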