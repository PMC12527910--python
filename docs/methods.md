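# Methods

This note documents the models, conventions and numerical choices behind
each pipeline, what the synthetic generators do and do not emulate, and the
known limitations. Units throughout: lengths µm, times s, forces N,
deflection nm, moduli Pa. Arrays are (t, y, x) for movies and (z, y, x)
for volumes; voxel sizes are given in the same axis order.

## Synthetic data: what it emulates

Every generator takes an explicit integer seed (no global RNG state),
records all parameters and the seed in a `GroundTruth`, and is
bit-reproducible. The generators emulate the *geometry and statistics*
that each measurement responds to — boundary displacement amplitude,
ellipsoid compression, anomalous-diffusion scaling, Hertzian loading with
a hidden contact point, spot intensity fractions — not photorealistic
microscopy. No point-spread function beyond Gaussian spots, no camera
noise model, no 3D tracking. Passing recovery tests therefore shows the
*measurement* logic is unbiased at realistic SNR and sampling, not that
upstream segmentation or tracking (which are inputs here) would be.

### Fluctuating boundary movies

The boundary is synthesized in polar coordinates,
`r(θ,t) = R + Σ_k [a_k(t)cos kθ + b_k(t)sin kθ]`, k = 2…n_modes+1, with
per-frame amplitudes i.i.d. `N(0, σ_r²/n_modes)`. Using a cos/sin pair of
equal variance per mode makes the pointwise temporal standard deviation of
the radial displacement exactly `σ_r` at every angle — the analytic truth
the pipeline must recover. Modes start at k = 2 because the k = 1 pair
is, to first order, a rigid translation of the boundary: drift
registration removes it (correctly), so including it would make the
recorded truth unrecoverable by construction. Defaults (R = 5 µm,
σ_r = 0.05–0.4 µm, 200 frames, 0.15 s frame interval, 8 modes) sit in the
range observed for pluripotent-cell nuclei imaged at high frame rate.
Rigid drift and exponential bleaching are applied after shape synthesis.

### Ellipsoid stacks

Nuclei are voxelized ellipsoids (voxel-centre-inside test), centres
snapped to voxel centres so discretization error is phase-coherent across
resolutions (otherwise the sub-voxel placement phase makes the error
non-monotone when the voxel size is halved). Compression by factor f
scales the z semi-axis; the volume-preserving variant rescales x,y by
1/√f, the default volume-losing variant does not — both observed modes of
nuclear flattening (height loss with and without volume loss).

### Particle tracks

Brownian: per-axis Gaussian increments of variance 2DΔt. fBm: exact
fractional-Gaussian-noise covariance (Cholesky factor shared across
tracks), Hurst H = β/2, scaled so MSD(τ) = 4·D·τ^β. Confined: Brownian
steps with iterated radial reflection at a circular corral. Localization
noise is additive i.i.d. Gaussian per coordinate (the tracking noise model
of the upstream software is not specified anywhere, so this is a free
parameter, default 0); it inflates the measured MSD by 4·σ_loc² at every
lag, which the suite verifies against the generator.

### Force curves

The piezo approaches at fixed sampling in z; past the hidden contact point
the travel is shared between indentation δ and cantilever bending d
(`z − z_c = δ + d`, `F = k·d`), with δ(z) solved by vectorized Newton
iteration to machine precision, so noiseless curves embody the contact law
exactly. Baseline tilt is added across the whole sweep; noise is Gaussian
in force. Defaults follow soft-cell practice: k = 0.01 N/m, 3 nN
setpoint, E around 0.5–4 kPa, 1000 samples per curve.

### Condensate scenes

A circular nucleus holds a uniform diffuse pool plus Gaussian spots whose
amplitudes are scaled analytically so the spot-added intensity is exactly
the requested fraction of total nuclear intensity. The truth condensate
mask is the union of discs of radius 2.5σ around the spot centres: the
~4% of spot mass outside the disc and the diffuse pool inside it nearly
cancel in the aggregation ratio (error budget: loss `exp(−r²/2σ²)` vs gain
`n·π·r²·(1−f)/(f·A_nuc)`), keeping true-mask recovery within a few percent
across fractions 0.1–0.5 with the default geometry (R = 5 µm, 4 spots of
σ = 0.1 µm at 0.05 µm pixels). An optional uniform camera offset exercises
background subtraction.

## Pipelines

### Envelope fluctuations

Bleach correction is simple-ratio to frame 0 on the mean foreground
intensity. Registration aligns each frame to frame 0 by mask centroid
(translation) and principal-axis orientation (rotation), resampling
bilinearly and re-binarizing at 0.5; below 5% relative anisotropy of the
second moments the orientation is shape-noise-dominated and "correcting"
it scrambles frames, so rotation is zeroed with a QC flag. Anchors
(default 16 — "multiple locations" made operator-free) sit at equal arc
length on the frame-0 contour; the edge position per frame is the
inside→outside 0.5 crossing of the bilinearly sampled mask profile along
the outward normal (0.25 px sampling, 3-sample moving average), linearly
interpolated. Crossing detection uses hysteresis bands (≥0.6 solidly
inside, ≤0.4 solidly outside) so interpolation wiggle is not mistaken for
a double crossing, while a genuine exit-and-re-entry is still flagged NaN,
never imputed. Per-anchor SD uses the population (1/T) convention;
anchors with >20% missing crossings are excluded. Profiles are 1 px wide
(no line-width averaging).

### Morphometry

Volume = voxel count × voxel volume; height = z-slice extent × voxel_z
(matching a z-stack measurement, not a fitted ellipsoid). Surface area
defaults to a marching-cubes mesh of the 0.5 iso-surface after a 1-voxel
Gaussian smoothing — smoothing suppresses the ~+10% staircase bias of
meshing a binary mask directly; voxel-face counting is kept as a
deliberately simple cross-check and overestimates smooth shapes by up to
~1.5×. Which variant published surface-to-volume figures used is
generally unstated; both are provided. Segmentation is an input — the
included Otsu labeller exists only for self-contained demos.

### Microrheology

Per-track time-averaged MSD (ensemble mode available); gapped tracks
contribute only pairs whose both frames exist. The power-law fit is OLS in
log-log space over lags 2–10 by default: lag 1 carries the largest
relative localization-noise bias, and the short-lag restriction keeps the
fit in the regime where the time-averaged MSD is well estimated. The 2D
convention MSD = 4·D_eff·τ^β is fixed and documented (the factor is
dimensionality-dependent and often left implicit). Analysis is 2D only,
matching single-focal-plane imaging at ~100 ms intervals.

### AFM

Baseline: straight-line fit to the first 30% of the approach with robust
iterated outlier rejection, so a window that accidentally reaches past
contact does not tilt the baseline; the residual SD becomes the noise
scale for detection. Contact detection (noise_threshold): first sample
exceeding 3×SD for 5 consecutive samples, refined by regressing F^(1/p)
(p the contact-law exponent of the assumed geometry) on tip–sample
displacement and back-extrapolating to zero force — exact on noiseless
curves. A variance-ratio detector is available as a cross-check.
Indentation δ = (z − z_c) − d. The Hertz fit is linear in E at fixed
contact offset, so the residual offset is found by bounded 1D minimization
wrapping a closed-form E solve — deterministic, no iterative-convergence
failure modes; fits with E ≤ 0 or too few points are flagged invalid, and
force maps report the median of valid replicates.

Contact-point precision is baseline-limited: at 5 nm deflection noise
(0.05 nN at k = 0.01 N/m) a ±0.5 nm error in the fitted baseline offset
moves the apparent contact by tens of nanometres, an information limit no
estimator can beat (the maximum-likelihood forward fit attains the same
scatter); the modulus is insensitive to this because the residual offset
is co-fitted. At 0.1 nm deflection noise the detector localizes contact
to well under one sample spacing. Default geometry is the four-sided
pyramid (Bilodeau form, matching sharp silicon-nitride tips as assumed by
vendor software); since the true tip constant is rarely reported, fits
are conditional on the declared geometry/tip parameter and both
alternatives are selectable, never silently fixed. The optional
indentation-depth cap (10% strain rule) requires a sample height and is
off unless `max_indentation` is passed.

### Condensates

Relative aggregation divides background-subtracted intensity sums
(condensate mask over whole nucleus); the background is the camera/off-cell
level — constant by default, estimable as a percentile of outside-nucleus
pixels — while the diffuse nucleoplasm pool stays in the denominator. The
metric is invariant to intensity rescaling and monotone under mask
growth. Shell profiles use Euclidean-distance-transform banding: band i
covers signed boundary distances `(0.4 − i·0.15, 0.4 − (i−1)·0.15]` µm
(positive outside). Distance banding is isotropic, pixel-size-aware and
equivalent to the classic dilate-once/erode-repeatedly construction in the
continuum limit; the literal morphological mode is kept for cross-checks
and agrees when the physical steps are whole pixels. Physical distances
are converted by thresholding the distance map, never by rounding an
erosion count. The MAD-threshold detector is plumbing that stands in for
trained-model segmentation; it floors the threshold at a relative contrast
(default 5% above the nucleoplasm median) so noise-free images do not
degenerate, and externally supplied masks are the recommended path for
real data. Detected condensates are truncated at the nuclear boundary; no
halo is added around detected spots. Time courses optionally histogram-
match each frame's nuclear pixels to frame 0 (the standard bleach
correction for condensate movies) before measuring.

## Problem sizes

The acceptance script and end-to-end tests run at: 200-frame movies with
16 anchors (fluctuations, four amplitudes); a 5 µm sphere at 0.2 µm voxels
(volumetry); 500 tracks × 300 frames (rheology); 100 noisy + 50
low-noise + 3 noiseless curves of 1000 samples (AFM); 31k-pixel nuclei
(condensates) and 100 random blob shapes for the shell-geometry audit.
These sizes put Monte-Carlo error comfortably inside each stated tolerance
while completing in about a minute on one CPU.

## Known limitations

- Fluctuation sampling assumes a near-star-convex boundary; deeply
  invaginated envelopes produce flagged (excluded) anchors rather than
  measurements.
- Edge localization error (~0.3 px) adds in quadrature to the true
  amplitude; at 0.05 µm pixels this is negligible down to amplitudes of
  ~0.05 µm, below which recovery biases upward.
- The rheology module does not convert D_eff to viscosity (no GSER), and
  the AFM module fits elastic models only (no Ting/viscoelastic analysis).
- Proprietary instrument formats (JPK) and model-based segmentation are
  out of scope; data enter as plain TIFF/CSV tables.
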