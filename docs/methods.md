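# Methods

`mbrisk` implements a radiomic risk-stratification pipeline for pediatric
medulloblastoma-style MRI studies: per-region texture and surface-morphology
feature extraction from 3D tumor subcompartment masks, a combined radiomic
signature, penalized survival risk models, and leave-one-site-out
evaluation. Because multi-institutional pediatric MRI cohorts cannot be
redistributed, the package ships a synthetic phantom cohort generator with
known ground truth; every claim the test suite makes is a claim about that
generator plus the estimators, not about clinical data.

## Phantom cohort model

Each synthetic subject is a blob-shaped "tumor" in a 48³ voxel grid at
1 mm isotropic spacing (desk-scale; large enough that the largest habitat
plus filter margins fit with room to spare). The tumor has three nested
subcompartments mimicking the segmentation protocol of contrast-enhanced
T1 imaging:

* **non-enhancing tumor + cystic core** — the inner blob, radius drawn
  uniformly from 4.5–7 mm;
* **enhancing tumor** — a ~3-voxel shell around the core;
* **edema** — a further ~4-voxel shell.

The *habitat* is their union. Real segmentations have no such regular
geometry; nested shells are used so that every region has nonzero volume
for every subject, which keeps the per-region feature blocks complete.

Two latent standard-normal scores drive the phenotype:

* `z_tex` (texture disorder): intensities inside the tumor are
  `base + sigma * G`, where `G` is a unit-variance Gaussian random field
  (white noise smoothed with an isotropic Gaussian kernel, correlation
  length 2 voxels) and `sigma = 12 * exp(0.5 * z_tex)`. Across ±2 SD of
  `z_tex` the noise amplitude spans roughly 4.4–33 intensity units against
  region base intensities of 85/105/130 (core/edema/enhancing) and a
  background of 30: intra-tumoral disorder is visible but does not swamp
  the compartment contrast. The amplitude range was chosen so that the
  disorder signal is recoverable through the feature banks at the core's
  size (~600–1400 voxels); with much smaller amplitudes the region-boundary
  intensity steps dominate every texture map and the latent becomes
  unidentifiable at desk scale.
* `z_shape` (surface irregularity): the core radius is modulated by a
  random combination of degree-2..4 real spherical harmonics with relative
  RMS amplitude `0.08 * exp(0.5 * z_shape)` (degree 0 and 1 are excluded
  because they only rescale or translate the blob).

Survival is exponential proportional hazards,
`T ~ Exp(lambda0 * exp(beta_tex z_tex + beta_shape z_shape))` with
`lambda0 = 5e-4`/day (mean event time ≈ 2000 days) and uniform censoring on
[0, 3650] days, giving ≈ 45% observed events — plausible for long-term
overall survival in a pediatric brain-tumor cohort. Defaults:
`beta_tex = 1.0`, `beta_shape = 0.5`. The default cohort reproduces a
70-subject three-site structure (site 1: 14 Group 4 + 8 SHH; site 2:
18 + 13; site 3: 16 + 1).

Because the hazard coefficients affect only the survival draw, different
hazard settings (including the null `beta = 0`) can reuse one set of
generated images; `resimulate_survival_table` exists for exactly that.

What the phantom does **not** emulate: scanner contrast physics, bias
fields beyond a smooth polynomial, inter-site acquisition differences,
anatomical context, Chang staging, or realistic subcompartment volume
distributions (none are published for this population). Passing tests
therefore demonstrate estimator correctness and end-to-end signal
recovery under a known generative model — not clinical validity.

## Preprocessing

* **Bias correction**: least-squares polynomial (total degree ≤ 3) fit to
  log intensity over a body mask; the volume is divided by the
  exponentiated fit and the in-mask mean is restored. This is a low-order
  surrogate for spline-based inhomogeneity correction and is idempotent to
  within tolerance. The fit subsamples to ≤ 40k voxels (ample for 20
  coefficients).
* **Intensity standardization**: histogram-landmark (Nyul-style) piecewise
  linear mapping. Landmarks are the 1st/99th percentiles plus deciles
  10–90; the standard scale is the across-volume mean of each landmark.
  Linear extrapolation beyond the end landmarks; strictly monotone. Inside
  the experiment pipeline this step is applied fold-wise (training sites
  only) when enabled; the phantom experiments skip it by default because
  generated volumes share an intensity scale by construction, and per-fold
  re-extraction would triple compute for no change in behaviour.
* **Resampling**: trilinear for intensities, nearest-neighbor for label
  masks, affine updated; a no-op when the spacing already matches.

## Texture features (1070 per region)

214 per-voxel definitions × 5 first-order statistics (mean, median, SD
with n−1, Fisher skewness g1, excess kurtosis g2; a constant map yields
SD = skewness = kurtosis = 0):

| family   | maps | notes |
|----------|------|-------|
| gradient | 13   | central differences, gradient magnitude, Sobel x/y/z + magnitude, Laplacian, 3³ local mean/SD/range, max directional (Kirsch-style) response over the 13 cube directions |
| Haralick | 13   | per-voxel GLCM in a 5³ window: intensities quantized to 64 levels over the region min–max, 13 symmetric unit-cube offsets pooled into one symmetric normalized matrix; the 13 classical statistics |
| Laws     | 125  | all 5³ separable combinations of L5/E5/S5/R5/W5; energy = local mean of |response| over a 5³ window |
| Gabor    | 50   | per axial slice, complex response magnitude at 5 wavelengths (2–32 voxels) × 10 orientations; ~1-octave bandwidth (σ = 0.5622 λ); envelopes normalized to unit gain so responses are comparable across scales; DC response exactly zero |
| COLLAGE  | 13   | per slice: dominant gradient orientation per pixel from the 5×5 structure tensor, quantized to 64 bins over [0, π); co-occurrence of bins over a 5×5 window (4 symmetric 2D offsets); the same 13 statistics — entropy is the "gradient entropy" |

Numerical conventions: replicate padding for all convolutions; log base 2
with 0·log 0 = 0; a degenerate (single-cell) co-occurrence matrix yields
energy 1, entropies 0, correlation 0; pixels with a vanishing structure
tensor take orientation bin 0. Gabor kernels are applied as separable
complex 1D convolutions (the isotropic envelope factorizes), with the DC
term removed via an exact box-mean correction. Haralick windows pool only
voxel pairs whose *both* endpoints lie inside the window and the region
mask.

Because quantization is min–max over the region, Haralick and COLLAGE maps
are invariant to affine intensity changes — including a pure amplitude
scaling of the noise field. Amplitude information travels through the
gradient, Laws and Gabor families; co-occurrence families respond to
changes in the field's *structure* (correlation length, anisotropy).

## Shape features (34 per region)

The isosurface is extracted by marching cubes at level 0.5 of the mask
indicator after a σ = 0.5 voxel Gaussian smoothing, followed by 10
small-step (0.1) uniform Laplacian smoothing iterations; meshes are
watertight and outward-oriented, with areas in mm².

Per-vertex curvature comes from a polynomial patch fit in the local
tangent frame (z along the *inward* normal, so convex surfaces have
positive curvature): neighbors within 8 mean edge lengths, terms up to
order 4 (the cubic/quartic terms absorb the truncation bias a pure quadric
incurs on curved patches). The first and second fundamental forms of the
fitted patch give K and H; principal curvatures are
`H ± sqrt(max(H² − K, 0))`. On a digital r = 10 sphere this lands within
~3% of the analytic curvatures; below r ≈ 6 the estimates are
resolution-limited (the patch becomes comparable to the object) — a known
limitation at 1 mm spacing, shared by the phantom cores.

Local descriptors: curvedness `C = sqrt((k1²+k2²)/2)`, sharpness
`S = (k1−k2)²`, total curvature `T = k1²+k2²`, and the shape index
`SI = (2/π) arctan((k1+k2)/(k1−k2))` with `k1 ≥ k2`, `SI = sign(H)` at
umbilic points and 0 on a plane, so a sphere scores +1, a cylinder +1/2.
The sharpness and total-curvature formulas are declared conventions (the
standard curvature-difference and bending-energy densities). The four
local features are aggregated with the same 5 statistics as texture maps.

The 14 global contour features use millimetre units and the
solid-ellipsoid convention (axis length = 2√(5λ) from the voxel-coordinate
covariance eigenvalues): volume, major/minor axis length, eccentricity
√(1−λ3/λ1), elongation √(λ1/λ2), flatness √(λ2/λ3), orientation (first
principal axis vs. x, folded into [0, π/2]), perimeter (mesh area),
roundness, equivalent spherical radius and diameter, elongation shape
factor, compactness `36πV²/A³`, and integrated intensity. Roundness and
compactness are clipped at 1: voxelization can push a digital ball's mesh
area marginally below the isoperimetric bound.

## Risk models and evaluation

Per experiment cell (subgroup × region × feature set × held-out site):
features are z-scored with training-set statistics (zero-variance columns
dropped and recorded), then an elastic-net-penalized model is fitted —
LASSO (α = 1), ridge (α = 0) or elastic net (α = 0.5). The default
selection outcome is penalized logistic regression on the event indicator;
a penalized Cox mode on the censored times is a configuration switch
(scikit-survival's Coxnet). λ is tuned by stratified 5-fold
cross-validated deviance over a glmnet-style descending grid (15 points,
λ_min/λ_max = 0.01), fold assignment seeded. The risk score is the linear
predictor; the stratification threshold is the *training*-score median.
Held-out subjects above the threshold are "high risk"; the groups are
compared with the Kaplan–Meier product-limit estimator, the two-group
log-rank test (χ², 1 df), a univariate Cox hazard ratio (Newton on the
Breslow partial likelihood; Wald 95% CI; separation reported via a capped
coefficient), and Harrell's C over permissible pairs (tied scores credit
1/2; higher score ⇒ predicted shorter survival). Censored subjects remain
in the risk set at their censoring time; p-values are two-sided; a dataset
with no events yields log-rank p = 1 by convention.

Nothing derived from the held-out site ever reaches the fit: scaling,
λ selection, coefficients and threshold are functions of the training
sites alone, and a test asserts bit-identical fits under perturbation of
the held-out data.

Cells whose training or test subgroup stratum has fewer than 3 subjects
are skipped and logged (the default cohort's site 3 has a single SHH
subject, so SHH/site-3 folds skip, mirroring how sparse strata must be
handled in the real design). A cell whose held-out scores all fall on one
side of the threshold is flagged invalid rather than reported.

## Verification experiments and problem sizes

The acceptance-level tests run, per seeded replicate (10 replicates), a
full 70-subject cohort with `beta_tex = 1.5`; the Group 4 stratum (48
subjects) of the core region is extracted and evaluated leave-one-site-out
with all three models on the combined signature. The core region is used
because it is the smallest compartment (~600–1400 voxels), keeping ten
replicates tractable on one CPU; the same code path handles any region.
The null arm re-simulates survival with both hazard coefficients zeroed on
the same features, and the texture-vs-shape comparison re-simulates with
`beta_shape = 0` so the hazard is texture-driven only.
`scripts/acceptance.py` re-runs one such replicate end to end, plus the
analytic curvature oracles and a 500-simulation log-rank null calibration.

## Known limitations

* Curvature (hence local shape features) is biased for structures below
  ~6 mm radius at 1 mm spacing; phantom cores sit near this limit, which
  damps — but does not remove — the shape signal.
* Haralick/COLLAGE invariance to amplitude means pure noise-amplitude
  phenotypes are carried by the other three families; a phenotype that
  changed only field *structure* would show the reverse pattern.
* Gabor and COLLAGE are 2D per-axial-slice by design (matching axial
  acquisitions with thick slices); no 3D variants.
* The exponential survival generator has proportional hazards by
  construction; model misspecification robustness is untested.
* Log-rank power at site-level test sets of 14–18 subjects is modest, so
  single-fold significance is noisy; conclusions in the verification
  experiments are drawn across replicates.
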