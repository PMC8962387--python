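# Methods

`perfcell` quantifies how far cerebral perfusion predicts where
intra-arterially infused, iron-labeled cells lodge in the brain. It has three
analysis stages — dynamic susceptibility-contrast (DSC) perfusion mapping,
SWI-based cell-density mapping, and voxelwise correlation statistics — plus a
digital phantom that generates all three input modalities with known ground
truth, so every stage can be validated quantitatively without animal data.

## Tracer-kinetic model and perfusion maps

The tissue model is the standard indicator-dilution relation

    C(t) = (CBF / 6000) · (AIF ⊛ R)(t),        R(t) = exp(−t / MTT),

with CBF in mL/100 g/min (the /6000 converts to 1/s), the arterial input
function (AIF) in mM, and a mono-exponential vascular residue function. The
central volume theorem ties the three parameters together: CBV = CBF·MTT/60
(mL/100 g). Measured T2*-weighted signal follows
S(t) = S0·exp(−TE·k·C(t)) + ε with k the susceptibility-contrast constant
(default 140 (mM·s)⁻¹, chosen so tissue bolus drops are 30–50% of baseline)
and ε additive Gaussian noise (default SD = S0/20, i.e. SNR 20).

The analysis side never sees the ground truth. It converts signal to relative
concentration by C = −ln(S/S0)/TE (unit proportionality constant: every
downstream statistic is rank- or regression-based, so only relative perfusion
matters), and computes eight maps:

* pre-deconvolution "basemaps": **TTP** (time of the concentration peak from
  bolus arrival, earliest frame on ties), **ΔS/S** (normalized maximal signal
  drop), **MS** (maximum signal downslope per frame pair), **CBV-AUC**
  (trapezoidal area under C(t) from the bolus frame to the end of the series);
* truncated-SVD deconvolution maps: the lower-triangular Toeplitz matrix
  A[i,j] = TR·AIF(t_{i−j}) is inverted with singular values below
  `trunc_frac`·σ_max zeroed, giving the scaled residue r(t) per voxel, and
  **CBF-sSVD** = max r, **Tmax-sSVD** = argmax r·TR, **CBV-sSVD** =
  ∫C/∫AIF, **MTT-sSVD** = CBV/CBF (the central-volume closure holds exactly
  by construction).

Maps are cropped to the brain mask (out-of-brain voxels become NaN) and then
median filtered (radius 1, NaN-ignoring); cropping first keeps out-of-brain
zeros from leaking into edge-voxel medians.

### Residue discretisation

On the TR grid the simulator keeps the exponential residue shape with
R[0] = 1 but rescales the k ≥ 1 tail by a constant so that TR·ΣR = MTT
exactly. This is the only discretisation for which the two identities the
package tests — peak-residue flow recovery (needs R[0] = 1) and discrete
tracer-mass conservation AUC(C)/AUC(AIF) = CBV/100 (needs the exact area) —
hold simultaneously; raw point sampling distorts the area by a factor
x/(1−e^(−x)), x = TR/MTT, which reaches +58% at MTT = TR, while
bin-integrating the exponential depresses R[0] by up to 37%.

### Truncation threshold

`trunc_frac` trades noise amplification against systematic underestimation of
CBF. The config default is 0.2, the common literature/processing-software
default. Measured on this phantom, the truncation bias alone at 0.2 is ~20%
of CBF (median over the brain), so the package's recovery experiments use a
threshold matched to the data's noise level: 0.05 for noiseless series (max
CBF error 3.1% where MTT ≥ 2·TR; CBV error at floating-point level) and 0.1
at SNR 20 (median CBF error ~7% after the median filter). Rank-based
statistics are insensitive to this choice (Spearman between recovered and
true CBF is > 0.95 even at 0.2).

### Bolus detection

The brain-mean signal is scanned forward; the first frame falling more than
3 running-baseline SDs below the running baseline mean — sustained for two
consecutive frames, so a single noisy frame cannot truncate the baseline —
marks arrival, and the frame before it is `bolus_frame`. S0 is the per-voxel
mean over frames [0, bolus_frame). Accurate baseline estimation matters more
than it may appear: a 1.6% S0 error becomes a constant concentration offset
that accumulates over all ~210 post-bolus frames of the AUC.

### AIF

Deconvolution needs an input function. Automatic selection ranks in-brain
voxels by peak height/(TTP + TR) — tall, early peaks — and averages the top
five curves; the phantom plants a small "arterial" voxel cluster carrying a
scaled copy of the true AIF so that this search has a physically sensible
target. A manual voxel list, or a curve supplied directly (e.g. the phantom's
ground-truth AIF), bypasses the search.

## Cell-density arm

Iron-oxide-labeled cells shorten T2* and appear as focal hypointensities on
the post-infusion SWI. The chain is:

1. **Rigid registration** of post to pre SWI by normalized cross-correlation
   (NCC): integer-shift search on a 2× downsampled grid seeds a Nelder-Mead
   refinement over 3 rotations + 3 translations; NCC is evaluated over the
   valid overlap only (zero-filled out-of-field voxels would dominate it
   otherwise). If the optimum improves NCC by < 1e-3 over identity the
   identity transform is returned with a warning — the correct behavior both
   for already-aligned volumes and for registration failure on structureless
   data. The 4×4 world matrix is saved as plain text.
2. **Difference mask**: voxel is cell-positive when the fractional drop
   (pre − post)/pre exceeds `drop_threshold` (default 0.2; relative, hence
   robust to global scanner rescaling) inside the brain mask. Under pure
   Gaussian noise at SNR σ/B the false-positive rate is the analytic tail
   Φc(thr·B / (σ·√(1+(1−thr)²))) ≈ 9·10⁻⁴ at SNR 20 — isolated voxels that
   the next step removes.
3. **Cleaning**: 26-connected components smaller than `min_size` voxels
   (default 2) are removed — a deterministic replacement for interactive
   mask curation.
4. **Density map**: the binary mask is convolved with a normalized spherical
   kernel (radius 0.45 mm ≈ 1.5 in-plane perfusion voxels), giving the
   fraction of cell-positive SWI voxels per neighborhood in [0, 1]; the
   result is mean-pooled onto the perfusion-map grid (densities are averages,
   not intensities) and median filtered (radius 1). Values below half of one
   voxel's kernel weight are zeroed — they can only be FFT roundoff, and
   "density > 0" is used downstream to delineate the accumulation region.
5. **Accumulation region**: positive-density voxels, morphologically closed
   (radius-1 ball) and intersected with the brain mask — the analysis mask
   restricted to where cells were actually detected.

## Statistics

Within an animal, each of the eight maps is compared with the density map
voxel by voxel under two masks (whole brain; accumulation region): Spearman's
ρ (average ranks on ties, t-approximation p) and the adjusted R² of the
simple OLS regression density ~ map, with its overall F-test p. NaN voxels
are dropped pairwise; degenerate combinations (constant map, empty mask)
yield NaN rows flagged `excluded`, never silently removed. Rows with both
p-values < α = 0.05 are flagged `significant`; the cohort summary (mean ± SD
over animals, sample SD with n−1) can filter on that flag, mirroring the
reporting convention of keeping only significant parameters. Voxels are the
correlation unit within an animal; animals are the unit between groups. A
pooled-voxel mode (concatenating voxels across animals) is provided as an
alternative reading of the cohort correlation; per-animal is the default.

The intact-vs-stroke comparison uses the two-sided Mann–Whitney U test on
per-animal whole-brain ρ, with exact enumeration of all C(n1+n2, n1) rank
assignments (midranks, so ties and identical groups are handled exactly)
whenever both groups have ≤ 8 animals, and Benjamini–Hochberg FDR across the
eight maps at α = 0.05.

Voxelwise p-values treat voxels as exchangeable. Under spatially smooth
fields that assumption is optimistic and the voxel-level tests are
anticonservative; the package therefore calibrates its type-I behavior at
the level where exchangeability genuinely holds — the animal-level group
comparison — by simulating null cohorts (coupling 0) and checking that the
Mann–Whitney rejection rate at α = 0.05 stays within the binomial band
(measured: 0.058 pooled over maps, 200 cohorts).

## The digital phantom

* **Fields**: CBF and MTT are independent Gaussian-filtered white-noise
  fields (FWHM 4 voxels) mapped affinely into 30–120 mL/100g/min and
  1.5–6 s inside an ellipsoidal brain; CBV follows from the central volume
  theorem. Because CBV = CBF·MTT/60 inherits both fields, the "timing" maps
  are *not* independent of CBV (rank correlation ~0.6–0.7 between CBV and
  MTT), which is why the amplitude-vs-timing contrast is tested as an
  ordering, not as zero timing correlation.
* **Stroke**: a contiguous ball in the injected (right) hemisphere with CBF
  ×0.3 and MTT ×2, CBV recomputed.
* **Acquisition**: 220 frames at TR 1.5 s, TE 15 ms, 10 pre-bolus baseline
  frames; gamma-variate AIF (α = 3, β = 1.5 s, peak 5 mM) delayed to arrive
  exactly at the end of the baseline. Noise is additive Gaussian on the
  magnitude signal (not Rician) for tractability, default SNR 20.
* **Grids**: perfusion voxels 0.3×0.3×0.6 mm, SWI voxels 0.15 mm isotropic —
  a 2×2×4 integer refinement, so mean pooling is exact block averaging.
  (The in-vivo protocol this emulates used a 1 mm perfusion slice and
  ~0.14 mm SWI voxels; the integer ratio is a deliberate simplification that
  changes nothing about the tested methods.)
* **Cell spots**: `n_cells` spherical spots (radius 1 SWI voxel, signal ×0.5)
  placed in the injected hemisphere with a 5% contralateral leak. Placement
  probability is exp(3·z) with z = w·u + √(1−w²)·g, where u are the
  normal-scores of CBV in the support and g those of an independent smooth
  field. The mixing weight w is calibrated (offline, by bisection at the
  default geometry with 2000 spots; frozen as a table) so that the realized
  rank correlation between local spot density and CBV approaches the
  requested `coupling`: w = 0/0.40/0.74/0.97 for coupling 0/0.3/0.6/0.9.
* **Realized coupling** is defined and measured over the injected hemisphere
  ∩ brain — the blood-supply territory of the infusion. The contralateral
  leak is uniform by construction, so including the contralateral hemisphere
  would dilute any achievable correlation to ≲0.36 regardless of the
  programmed coupling; restricting to the territory is also what the
  accumulation-mask analysis approximates on real data. The generator's
  ceiling (w = 1, 2000 spots) is ρ ≈ 0.83: Poisson placement noise bounds
  what 2000 spots can express, so a requested coupling of 0.9 saturates
  below its target (monotonicity is preserved).

### What the phantom does not model

No arrival-delay or dispersion variation (hence Tmax is identically 0 and
carries no usable contrast on synthetic data — its correlation rows are
excluded as degenerate), no vascular tree or partial-volume arteries beyond
the marked AIF cluster, no contrast leakage through a broken blood-brain
barrier, no Rician noise floor, no motion between or within acquisitions
(registration is still exercised, and recovers deliberately applied shifts
in tests). Passing tests therefore demonstrate correctness of the analysis
chain under the stated model, not robustness to everything real data does.

## Problem sizes and reproducibility

The validation experiments run at sizes chosen to keep the full suite fast
while leaving the statistics meaningful: parameter recovery on a 32×32×8
phantom with the full 220-frame protocol; coupling recovery on 32×32×12
phantoms with 2000 spots (8 noiseless seeds for the level, 20 noisy seeds
for the amplitude-vs-timing ordering); type-I calibration on 200 cohorts of
nine 16×16×8 animals with 60-frame series and 300 spots. Every generator is
a pure function of its seed; the `demo` subcommand (3 intact + 3 stroke
animals, 24×24×8, 120 frames, coupling 0.6, seed 7) reproduces the committed
reference CSVs bit-for-bit on repeated runs and to 1e-8 across machines.

## Known limitations

* Relative, not absolute, quantification: no hematocrit/density constants,
  so CBF/CBV maps are in scaled units (the phantom's known scale factors are
  used only for validation).
* The standard (non-circulant) SVD deconvolution is delay-sensitive by
  design; with delayed tissue curves it would underestimate CBF.
* MS is the most noise-fragile map (an extreme-value statistic over ~220
  frame differences); at SNR 20 its rank correlation with ground truth is
  weak.
* The exact Mann–Whitney enumeration is O(C(n1+n2, n1)) and is capped at
  8 animals per group; larger groups use the tie-corrected normal
  approximation.
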