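# Methods

This note documents the models, parameters and numerical choices behind
`nucratio`, and what the synthetic-data tests do and do not demonstrate
about real data.

## The measurement model

A ratiometric nuclear reporter pair (DII-VENUS, degradable; mDII-tdTomato,
non-degradable; same promoter) is imaged as a two-channel 3D confocal
stack. For a nucleus with full reporter output A (counts) and auxin-sensing
level expressed as a ratio r ∈ [0, 1], the ideal signal is mDII = A and
DII = r·A inside the nuclear volume. The pipeline estimates r per nucleus
as the ratio of mean intensities over the segmented nuclear volume, after a
single linear rescaling of the DII channel (below). The estimate is exact
for noise-free data because a nucleus' DII and mDII profiles are
proportional, a property preserved by any common blur — so segmentation
boundaries need not be perfect, only nucleus-pure.

## Synthetic data generator

The generator emulates the study conditions the pipeline is meant for:
512-voxel-scale 12-bit stacks, 1 µm section spacing, two tissue bands
("adaxial" at low y, "abaxial" at high y) with per-domain true-ratio
distributions. Defaults:

| parameter | default | why |
|---|---|---|
| grid (z, y, x) | 32 × 128 × 128 voxels | one cropped leaf-side volume at workable size |
| spacing | (1.0, 0.5, 0.5) µm | 1 µm sections; 0.5 µm is a typical 25× pixel size (the true xy size is not recoverable from the stack format, so it is a config value) |
| nuclei / stack | 100 adaxial + 74 abaxial | pooled targets of 2006 / 1475 nuclei over 20 stacks |
| ratio dist. | adaxial mean 0.24 SD 0.20; abaxial 0.29 / 0.24 | the group moments to be recovered |
| radius | 1.2–2.0 µm | small plant nuclei at this resolution |
| amplitude | 1000–3000 counts | mid-range of a 12-bit detector |
| background | 10 counts | near-dark photon-counting detector offset |
| noise | Poisson (signal+background) then Gaussian SD 5 | shot noise then read noise; order fixed for reproducibility |
| PSF | Gaussian confocal model, NA 0.95, 514/527 nm | same optics the restoration assumes |

Two modeling choices deserve emphasis:

**Moment-matched truncation.** The target mean/SD are moments of the
*observed, bounded* ratio distributions, so the generator solves for the
pre-truncation normal whose [0, 1]-truncated law has exactly the requested
mean and SD (2-equation root find on `truncnorm` moments; sampling is
exact via the truncated quantile function). Feeding the printed moments in
as pre-truncation parameters would inflate the realized means by ≈ +0.04
at these settings. For the abaxial target the solution is an extreme tail
(µ ≈ −11.7, σ ≈ 2.06): a monotone-decreasing density on [0, 1], which
matches the long-tailed shape of low-auxin-signal distributions.

**Calibration fiducial.** Max-matching normalization (below) recovers
ratios only up to the scale set by the brightest DII nucleus. One nucleus
per stack therefore carries true ratio 1.0 at 1.15× the top amplitude, so
both channel maxima fall inside it and the normalization is anchored at
unit scale; were it merely tied for brightest, extreme-value competition
among ~175 nuclei biases the scale by ≈ +1%. The fiducial is excluded
from tissue statistics by its known position — it is a scale reference,
not tissue.

The generator does **not** model spherical aberration, depth-dependent
attenuation, bleaching, nuclear texture, elongated or dividing nuclei, or
touching/overlapping nuclei (placement enforces ≥ 1 µm surface
clearance). Passing the recovery tests therefore shows the pipeline is
correct under its own forward model, not that segmentation would be as
clean on crowded real tissue; the merge/removal refinements exist
precisely for the harder real case.

## Preprocessing

The pre-segmentation chain is deconvolution (optional) → Wiener
(optional, off by default) → voxelwise-maximum merge of the two nuclear
channels → Otsu mask → median (1 pass, radius 1) → Gaussian (1 pass,
σ = 1 voxel). The sequence is fixed; all counts/radii are config values.
Quantification always reads the *unprocessed* reporter channels —
restoration only serves segmentation.

* **PSF**: paraxial Gaussian approximation of the confocal PSF; lateral
  SD 0.21·λ/NA per wavelength, axial 0.66·n·λ/NA², excitation and
  emission combined in quadrature; kernel truncated at 4 SD (> 99% mass)
  and normalized. At NA 0.95 with 0.5 µm pixels the blur is sub-voxel —
  realistic for this sampling, which also means deconvolution is a mild
  sharpening rather than a rescue.
* **Richardson–Lucy** is implemented as the standard multiplicative EM
  loop with every internal convolution reflect-padded (FFT convolution on
  a padded copy, cropped back). This makes a uniform image an exact fixed
  point and keeps borders consistent across iterations; library
  implementations using zero-boundary convolutions accumulate border
  error with the iteration count. Flat-sheet initialization at the image
  mean; 8 iterations by default.
* All convolution-like operations use reflective padding; none can
  produce negative intensities.

## Segmentation

Every in-mask voxel takes as parent the in-mask neighbour maximizing
(I_neigh − I_current) / ‖x_neigh − x_current‖ with physical distances, so
a 1 µm z-step is not treated like a 0.5 µm x-step. Decisions the
formulation leaves open:

* **Tie-break**: equal best slopes resolve to the lexicographically
  smallest (z, y, x) offset — deterministic and independent of visiting
  order (parents are defined pointwise; the implementation is a
  vectorized sweep over offsets, verified against a per-voxel scan).
* **Plateaus**: a voxel whose best slope is ≤ 0 is its own attractor.
  Flat plateaus fragment into singletons by design and are reunified by
  the merge steps; strict ascent keeps the parent graph acyclic.
* **Depth merge**: the intensity depth of an adjacent pair is
  f(max_A, max_B) − min(boundary intensity), boundary = voxels of either
  object adjacent to the other. `f = min` by default (the weaker object's
  depth governs, merging shallow sub-peaks); `f = max` is a config
  switch. Merging repeats until stable; label counts never increase.
* **Refinement order** (configurable): distance merge → depth merge →
  small-to-closest → remove by size → remove by intensity. Defaults:
  attractor merge within 2 µm, depth merge off, absorb objects < 4 µm³
  into a larger object within 3 µm, remove < 2 µm³.

## Quantification

* **Normalization scope**: max-matching is computed over the labeled
  voxels of the processed volume (per crop). Whether to normalize per
  crop or jointly per leaf is exposed in config; per crop is the default
  since each cropped volume is processed independently.
* **Ratios > 1** are flagged, never clipped; with noise, ratios slightly
  above 1 are expected near the scale anchor.
* **Filters**: minimum mean mDII defaults to the 5th percentile of the
  per-nucleus mDII means (an adaptive floor against background
  fragments); volume bounds 2–500 µm³ (true volumes are 7–34 µm³;
  the wide upper bound only rejects gross fusions). No background
  subtraction by default; a constant-subtraction option exists.
* **Domains**: a record takes the tag of the first ROI polygon containing
  its (y, x) centroid, boundary inclusive; polygons are drawn on a
  reference slice and applied through z (median-slice demarcation).
  Centroids in no ROI are "discarded".

Residual biases under the default noisy conditions: including background
voxels in segmented objects pulls ratios toward 1 by roughly
b·(1−r)/(b + A·f) ≈ +0.007 at background 10 and effective in-object
signal ≈ 700 counts. The 20-stack recovery test measures the pooled
effect (≈ +0.01 on group means, well inside its 0.02 band).

## Statistics

* **AUC**: normalized rank-sum over all cross pairs, computed from
  midranks of the pooled sample (exact under ties). Antisymmetric;
  exactly 0.5 for a distribution against itself. A trapezoid
  rank-curve construction is exposed as an alternative reading but is
  not the default.
* **Quantiles** for violin/box numbers use linear interpolation; whiskers
  extend to the most extreme point within 1.5 × IQR.
* Reporting rounds ratios and SEM to three decimals. A single-value group
  reports SD 0 with an explicit flag. No hypothesis tests are computed —
  the comparison is deliberately descriptive.

## Problem sizes

Default test and recovery runs use 32 × 128 × 128 stacks with ~175 nuclei
and 20 replicate stacks (≈ 1.6 s per stack end-to-end, ≈ 35 s for the
recovery experiment), which gives pooled group sizes (~1700 / ~1300
after filtering) large enough that the pooled-mean standard error
(≈ 0.005) sits well below the 0.02 acceptance band.

## Known limitations

* The attractor sweep holds one float and one parent index per voxel per
  offset pass; very large stacks are bounded by memory, not time.
* Depth merging recomputes pair boundaries each outer iteration; with
  thousands of touching fragments it is the slowest refinement.
* ROIs are prisms through z (drawn on one slice); truly 3D domain
  boundaries need a per-slice ROI set.
* The Gaussian PSF model underestimates the Airy side lobes; for strongly
  aberrated data, supply a measured kernel to `richardson_lucy` directly.
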