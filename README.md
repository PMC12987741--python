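# fpetconn

Denoising and metabolic connectivity analysis for high-temporal-resolution
[¹⁸F]FDG functional PET (fPET).

## The problem

Constant-infusion fPET reconstructed at 1–3 s frames makes it possible to
correlate moment-to-moment fluctuations of the glucose signal between brain
regions ("metabolic connectivity"). At that frame rate the signal of
interest sits on top of a dominant cumulative tracer-uptake trend,
physiological oscillations (respiration ~0.3 Hz, cardiac ~1 Hz — which
*alias* into low frequencies when frames are 3 s long), motion-coupled
variance, and count-limited noise that scales with scanner sensitivity.
`fpetconn` is for researchers who need to remove those nuisance sources
before correlating regional time courses, and to quantify how filtering
choices, frequency bands and scanner sensitivity affect the resulting
connectivity matrices.

## What it implements

* **Unified component-based nuisance regression** — the core method. One
  design matrix per subject combines principal components of standardized
  voxel signals from the top 5 % of the white-matter and CSF probability
  maps, a PCA-compressed 24-parameter motion expansion (6 rigid-body
  parameters p, their backward differences ṗ, p² and ṗ²), and sine/cosine
  regressors at every Fourier-grid frequency outside a chosen pass-band
  [f_low, f_high]. Each voxel time course y is replaced by the residual of a
  single least-squares fit, ŷ = y − X(XᵀX)⁻¹Xᵀy, removing the uptake trend,
  tissue-borne physiological noise, motion variance and out-of-band power in
  one step.
* **Butterworth path** — order-4 band-pass IIR applied zero-phase to
  regional signals, with motion handled by partial correlation.
* **Connectivity** — parcel-mean extraction, Pearson and partial
  correlation matrices, strongest-edge lists, matrix comparison (Spearman /
  Pearson over the lower triangle), group means.
* **Spectral tools** — Welch PSDs after baseline-uptake removal, Nyquist
  arithmetic f_N = 1/(2·Δt) and the folding rule f_alias = min_n |f − n·f_s|.
* **Network statistics** — Ward clustering of connectivity profiles,
  cophenetic correlation, fixed-k cuts, cluster-overlap tables, and
  permutation split-half reliability with percentile intervals.
* **Synthetic fPET simulator** — bolus + constant-infusion uptake,
  band-limited correlated networks with exactly known ground-truth
  connectivity, CSF-weighted physiological oscillations, motion coupling
  and sensitivity-scaled pseudo-Poisson noise, for two scanner profiles
  (high-sensitivity 1 s frames; standard 3 s frames). See
  `docs/methods.md` for the model and its limits.

## Worked example

```python
import numpy as np
import fpetconn as fp

# simulate one high-sensitivity subject (1500 frames of 1 s) with a known
# 0.01-0.1 Hz network
subject = fp.simulate_subject(fp.SimulationConfig(seed=1))

# analysis window: discard the first 10 min of uptake
keep = subject.series.frame_onsets >= 600.0
series = fp.exclude_uptake_window(subject.series, 600.0)
motion = fp.MotionTrace(subject.motion.params[keep], series.frame_duration)

# unified nuisance design for the 0.01-0.1 Hz pass-band
band = fp.FrequencyBand(0.01, 0.1)
design = fp.build_compcor_design(series, subject.tissue_maps["WM"],
                                 subject.tissue_maps["CSF"], motion, band)
print(f"design: {design.n_frames} frames x {design.n_columns} regressors")

# one regression removes everything at once, then estimate connectivity
gm = subject.tissue_maps["GM"].prob >= 0.5
cleaned = fp.compcor_residualize(series, design, mask=gm)
regions = fp.extract_regional_timeseries(cleaned, subject.parcels)
matrix = fp.pearson_connectivity(regions, band=band)

rho, n_pairs = fp.compare_matrices(matrix, subject.truth.connectivity[0])
print(f"recovery of ground-truth connectivity: Spearman rho = {rho:.3f} "
      f"over {n_pairs} region pairs")

u = subject.truth.uptake[keep]
worst = max(abs(np.corrcoef(row, u)[0, 1]) for row in regions.values)
print(f"max |corr| with the uptake trend after denoising: {worst:.3f}")

tree = fp.ward_linkage(matrix)
print(f"cophenetic correlation of the Ward tree: "
      f"{fp.cophenetic_coefficient(tree, matrix):.2f}")
print(f"Nyquist at 3 s frames: {fp.nyquist_frequency(3.0):.3f} Hz; "
      f"0.3 Hz aliases to {fp.alias_frequency(0.3, 1/3):.3f} Hz")
```

Output:

```
design: 900 frames x 758 regressors
recovery of ground-truth connectivity: Spearman rho = 0.975 over 190 region pairs
max |corr| with the uptake trend after denoising: 0.015
cophenetic correlation of the Ward tree: 0.81
Nyquist at 3 s frames: 0.167 Hz; 0.3 Hz aliases to 0.033 Hz
```

Reading the numbers: the 900 retained frames carry 758 nuisance regressors
(tissue components, motion PCs, and a cos/sin pair per out-of-band grid
frequency). After the single regression, regional signals are essentially
uncorrelated with the injected uptake curve (|r| ≤ 0.015, versus > 0.99
before filtering), and the estimated 0.01–0.1 Hz connectivity matrix ranks
region pairs almost exactly as the simulator's ground truth does
(Spearman ρ = 0.975 over the 190 pairs of 20 regions). The sampling
arithmetic shows why 3 s frames alias a 0.3 Hz respiratory signal to an
apparent 0.033 Hz "connectivity" frequency.

## Command line

Every step is also exposed as a subcommand operating on NIfTI / TSV / JSON
artifacts:

```sh
fpetconn simulate --profile quadra --seed 1 --out sim/
fpetconn denoise --method compcor --series sim/series.nii.gz \
    --wm sim/tpm_wm.nii.gz --csf sim/tpm_csf.nii.gz --gm sim/tpm_gm.nii.gz \
    --motion sim/motion.txt --band 0.01 0.1 --out cleaned.nii.gz
fpetconn connect --series cleaned.nii.gz --parcels sim/parcels.nii.gz \
    --regions sim/regions.tsv --out mc.tsv edges.tsv
fpetconn psd ... ; fpetconn cluster ... ; fpetconn reliability ...
```

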