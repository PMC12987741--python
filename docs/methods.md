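# Methods

## Problem setting

Dynamic FDG-PET acquired under a bolus + constant-infusion protocol at frame
durations of 1–3 s ("functional PET") carries, besides the metabolic signal
of interest, a dominant cumulative tracer-uptake trend, physiological
oscillations (respiratory ~0.3 Hz, cardiac ~1 Hz), residual motion-coupled
variance, and count-limited noise whose magnitude depends strongly on
scanner sensitivity. Metabolic connectivity — the between-region correlation
of the denoised regional time courses — is only interpretable after these
structured nuisance sources are removed.

`fpetconn` implements two temporal denoising paths and the downstream
connectivity analysis:

1. **Unified component-based regression** (`nuisance` + `filters`). Per
   subject and analysis window, one design matrix is assembled from
   (a) principal components of standardized voxel time courses drawn from
   the top 5 % of the white-matter and CSF probability maps, (b) a
   24-parameter motion expansion (6 rigid-body parameters, backward
   differences, squares of both) compressed by PCA, and (c) sine/cosine
   regressors at every Fourier-grid frequency outside a chosen pass-band.
   Every voxel (or region) time course is replaced by its least-squares
   residual on this design in a single regression, which removes the uptake
   trend, tissue-borne physiological noise, motion variance, and
   out-of-band power in one step, avoiding the noise re-introduction that
   sequential filtering can cause.
2. **Butterworth band-pass** (`filters` + `connectivity`). Regional mean
   signals are band-passed with an order-4 Butterworth IIR (an order-4
   low-pass prototype mapped to a band-pass, i.e. 8 poles), applied
   zero-phase (forward–backward) by default; motion is then handled by
   partial correlation on the 6 rigid-body parameters when estimating
   connectivity.

## Nuisance model details

* **Tissue masks.** The top fraction (default 0.05) of nonzero-probability
  voxels per compartment, ties at the cutoff included — the rule is
  deterministic and independent of voxel ordering.
* **Tissue PCA.** Voxel time courses are mean-centered and
  variance-normalized before the SVD (correlation PCA) so high-activity
  voxels do not dominate. Components are kept until cumulative explained
  variance reaches `variance_target` (default 0.5 per compartment — "the
  majority of variance"), capped at 6. Component signs are fixed so the
  largest-magnitude voxel loading is positive, making designs reproducible
  bit-for-bit.
* **Motion.** Backward differences with a leading zero row; the 24-column
  expansion is standardized (zero-variance columns dropped) and compressed
  by PCA at `variance_target` 0.99, at least one component kept.
* **Frequency regressors.** Grid frequencies f_k = k/(T·Δt) of the
  *analyzed window* (after the 600 s exclusion), k = 1…⌊T/2⌋; a cos/sin
  pair is emitted for every f_k strictly outside [low, high]; the
  identically-zero sine at the exact Nyquist frequency (even T) is dropped
  and columns are mean-centered. Computing the grid on the cropped series
  makes the regression-based filter match the analyzed window exactly.
* **Assembly.** An intercept is prepended; a rank-deficient stack is
  repaired by a greedy left-to-right sweep that drops later dependent
  columns (logged), preserving provenance labels.

## Butterworth details

`scipy.signal.butter(4, [low, high], btype="bandpass")` in second-order
sections, applied with `sosfiltfilt` (reflected edge padding, length
3·(2·n_sections+1)). Zero-phase application was chosen because correlation
analyses are phase-sensitive; `causal=True` restores a single forward pass.
The bidirectional magnitude response equals the *squared* analytic order-4
band-pass curve |H(f)|² = 1/(1 + B(f)^8), B(f) = (f² − f_low f_high)/(f·(f_high−f_low));
tests verify agreement within 0.02 absolute across a sweep (small residual
deviations near the transition bands come from bilinear frequency warping,
which is exact at the pre-warped cutoffs).

## Spatial filters

Gaussian smoothing uses σ = FWHM/(2√(2 ln 2)) per axis in voxel units with
reflective boundaries (constants preserved exactly, frame sums to ~1e-6
relative). The extended dynamic non-local-means filter runs sequential
spatiotemporal passes (3×3×3 voxels × 3 frames, then × 5 frames; search
window equals the patch window) with weights w ∝ exp(−‖patch_i − patch_j‖²/h²)
normalized over the window, followed by 5 mm Gaussian smoothing. `h="auto"`
sets the bandwidth per pass to a robust noise-sd estimate (median absolute
temporal difference / 0.6745 / √2) times the patch element count. This is a
generic re-implementation with exposed parameters, not a bit-exact port of
any particular published kernel.

## Spectral analysis

Nyquist frequency 1/(2·Δt); aliasing f_alias = min_n |f − n·f_s|, which is
idempotent on [0, Nyquist]. PSDs use Welch's method (Hann window, segments
of T/4 samples, 50 % overlap, constant detrend) after baseline-uptake
removal, which defaults to cubic-polynomial detrending on a Legendre basis
(well-conditioned); a design-based alternative reuses the tissue-component
design. The estimator choice is an implementation decision — the upstream
analysis names only the quantity, not the method — and all parameters are
exposed.

## Network statistics

Region r's feature vector is row r of the connectivity matrix (its
connectivity profile). Ward linkage on Euclidean profile distances gives a
monotone merge sequence; the tree is scored by the cophenetic correlation
and cut into exactly k clusters (default 8: seven canonical cortical
networks plus one subcortical cluster) by undoing the last k−1 merges.
Split-half reliability randomly partitions each subject's retained frames
into two disjoint equal halves (odd T: extra frame to half 1; a
`contiguous` option splits first/second temporal blocks), estimates
connectivity per half, averages matrices across subjects per half, and
records the Pearson correlation of the two lower-triangle vectors; the
distribution over permutations (default 5000) is summarized by its mean and
2.5/97.5 percentile interval. Under a pure-noise null the per-permutation
correlations are mutually dependent (they reuse the same data), so a single
dataset's permutation mean scatters around zero with sd ~0.05–0.07; the
bundled checks therefore average over independent replicate datasets when
estimating the null centre.

## Synthetic data generator

The simulator emulates the signal composition of a constant-infusion fPET
scan; it is the package's validation instrument, with known ground truth.

* **Geometry.** A 24×24×16 voxel grid (2 mm voxels) with concentric
  ellipsoidal compartments: CSF "ventricle" core, WM shell, GM ribbon, with
  graded trapezoid membership so top-fraction thresholding selects
  compartment cores. Gray matter is split into 20 roughly contiguous
  angular/axial parcels by default (configurable, e.g. 114 to mirror a
  100-cortical + 14-subcortical atlas).
* **Uptake.** U(t) = A_b(e^{−t/τ_decay} − e^{−t/τ_rise}) + α·t·(1 − e^{−t/τ_sat}),
  with τ_rise = 15 s, τ_decay = 60 s, τ_sat = 300 s, α = 0.06 s⁻¹. A_b is
  scaled from `bolus_fraction` (default 0.2, echoing a 20:80 bolus:infusion
  administration split) against the infusion term's equilibrium level; the
  20:80 figure is a *dose* ratio, so the curve reproduces the protocol's
  qualitative signature (early hump, then a saturating quasi-linear ramp,
  non-decreasing after ~2 min), not an integral split. Tissue weighting
  GM:WM:CSF = 1.0:0.4:0.1.
* **Networks.** Band-limited latent factors are synthesized in the
  frequency domain (independent complex Gaussian coefficients on the
  Fourier bins inside the band, zero elsewhere), then orthonormalized, so
  their empirical covariance is exactly the identity and the ground-truth
  connectivity equals the normalized loading Gram matrix L Lᵀ exactly.
  Default: one network in 0.01–0.1 Hz, 3 factors, block-dominant loadings
  with the region→factor assignment shuffled per draw so independently
  drawn networks have uncorrelated truths. Amplitude 1 activity unit.
* **Physiology.** 0.3 Hz (amplitude 1.0) and 1.0 Hz (amplitude 0.5)
  sinusoids weighted by the CSF membership, sampled at the frame grid —
  at 3 s frames the 0.3 Hz component folds to |0.3 − 1/3| ≈ 0.033 Hz
  exactly as sampling theory predicts (the closed-loop checks isolate this
  plant by disabling the other sources).
* **Motion.** A 6-parameter random walk (steps 0.002 mm / 5·10⁻⁵ rad per
  frame) coupled additively into each voxel through a random gain vector
  (sd 0.5 on standardized parameters) — deterministic and testable, in
  place of resampling the volume.
* **Noise.** Gaussian with sd σ₀·√max(U(t), ε), σ₀ = 0.3 (pseudo-Poisson:
  variance tracks instantaneous activity), scaled by √(176/S) for a profile
  with NEMA sensitivity S kcps/MBq — the standard 3 s profile (15 kcps/MBq)
  is √(176/15) ≈ 3.43× noisier than the high-sensitivity 1 s profile
  (176 kcps/MBq, 1500 frames; the standard profile has 400 frames of 3 s).
* A single master seed drives all draws through fixed-order child streams;
  identical configs are bit-identical.

**What the generator does not emulate:** realistic anatomy or partial-volume
mixing, tracer kinetics beyond the phenomenological uptake curve, true
Poisson counting statistics, scanner-specific spatial correlation of noise,
or motion as actual volume resampling. Passing tests therefore demonstrate
that the pipeline recovers known band-limited correlation structure under
this noise model — not performance on real scans, whose nuisance structure
is richer.

## Problem sizes used in the bundled checks

The validation suite and `scripts/acceptance.py` run the full-size default
simulation (24×24×16 grid, 1500 frames of 1 s, 20 regions) for the recovery,
selectivity and method-agreement statistics; reliability statistics use
region-level simulations (20 subjects, 900 frames) and 200-permutation
distributions, with the 5000-permutation default reserved for the CLI.

## Known limitations

* The unified regression assumes nuisance sources are linearly separable
  from the signal of interest; shared variance between gray matter and the
  tissue-component subspace is removed with the noise.
* With very wide pass-bands and short windows the out-of-band regressor
  block can approach the frame count; the design assembler repairs rank but
  the residual degrees of freedom shrink accordingly.
* The edNLM weighting is a generic local re-implementation; parameters are
  exposed rather than calibrated against any reference output.
* Region order is kept as stored in the region table; any network-grouped
  ordering is a display concern left to the caller.
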