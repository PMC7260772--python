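# Methods

This note records the modelling choices behind `dosecast`: what each stage
assumes, which knobs matter, what the synthetic phantoms do and do not emulate,
and where the design was genuinely open.

## Coordinate and data conventions

World coordinates are millimetres in LPS orientation; voxel arrays are indexed
`(z, y, x)` with 0-based indices, and `spacing`/`origin`/`direction` follow the
SimpleITK `(x, y, z)` convention. Every pairwise computation happens after
resampling the atlas case onto the new patient's grid, so all metrics live on
one grid. Masks are one binary volume per structure (overlapping structures
such as whole lung ⊃ ipsilateral lung stay representable); dose is float cGy
with the prescription (default 5000 cGy) carried alongside. Case manifests are
JSON; volumes are NIfTI or MetaImage. Manifest grids must agree to within
1e-4 mm or reading fails naming the offending component.

## Registration chain

The atlas→patient mapping is `f_P(f_D(f_R(·)))`:

- **`f_R` (similarity transform).** Seven parameters (versor rotation,
  translation, isotropic scale), full-image mean-squared-deviation metric,
  regular-step gradient descent with parameter scales from physical shift,
  3-level pyramid (shrink 4/2/1, smoothing 2/1/0 voxels), geometric centred
  initialisation. The optimiser is deterministic (no metric sampling).
- **`f_D` (Demons).** Fast symmetric-forces Demons on the rigidly resampled
  atlas image; default a single full-resolution level with 60 iterations and
  Gaussian displacement-field smoothing of 1.5 voxels. A multi-level pyramid is
  configurable (`RegistrationConfig.demons_shrink_factors` /
  `demons_iterations`), but the single-level default proved markedly more
  stable for inter-patient thorax pairs at desk-scale grids: seeding a coarse
  pyramid level with an initial field repeatedly drove the symmetric-forces
  update into large spurious displacements, while one full-resolution pass cut
  the MSD by roughly an order of magnitude. Residual misalignment after `f_R`
  on these images is a few voxels, which is within single-level Demons capture
  range.
- **`f_P` (PTV constraint).** The same Demons machinery applied to the binary
  PTV masks, Gaussian pre-smoothed by 1 voxel so the step images have usable
  gradients; 50 iterations, single level. This stage implements the idea that
  the target region, which dominates plan optimisation, should dominate
  registration accuracy too.

Each stage is guarded to be non-worsening in its own objective — image MSD for
`f_R` and `f_D`, PTV Dice for `f_P`. If an optimisation ends worse than
identity (possible when anatomy differences exceed the transform model), the
stage degrades to identity with a warning rather than propagating a harmful
transform. MSD comparisons fill out-of-grid voxels with the floating image's
minimum intensity; filling with 0 against CT air (≈ −1000) would bias every
comparison toward the identity transform.

Dose is warped with trilinear interpolation and clamped at 0; displacement
fields are composed by chaining (resampling applies `f_P`'s field to the
point first, then `f_D`'s, then `f_R` — exactly how the staged pipeline
sampled the floating image). Warping is therefore linear in dose, which the
tests exploit.

## Similarity features

All 11 features are ≥ 0, minimal on a self-pair, and oriented so smaller means
more similar; Dice and P_ovz are stored as reciprocals for that reason, capped
at 1e3 (configurable) when the raw overlap is exactly zero.

- **OVH.** The overlap volume histogram of an OAR relative to the PTV is the
  empirical CDF of the signed Euclidean distance (negative inside the PTV,
  voxel-centre distance transform) of the OAR voxels. Two OVHs are compared as
  the mean absolute difference of their *inverse* curves at the 1–99% volume
  percentiles — the expansion distance at which each OAR reaches i% of its
  volume — giving a mm-valued quantity comparable across patients. The
  alternative orientation (volume fraction at matched distances) remains
  available (`ovh_msd(..., orientation="volume")`), because the comparison
  axis is a genuine modelling choice; the distance orientation is the default
  since it keeps units physical.
- **3D moment invariants.** Central moments are accumulated over mask-voxel
  centres in world mm and normalised by μ₀₀₀^((p+q+r)/3+1), which cancels the
  voxel volume and makes η scale-free; J₁–J₃ are the classical second-order
  rotation invariants and B₃/B₄ the third/fourth-order ones. Rasterisation at
  1 mm keeps the coefficient of variation of each invariant under 2% across
  arbitrary rigid motions and 1.5× scaling (verified in the tests on an
  asymmetric triaxial shape — a perfectly symmetric ellipsoid has identically
  zero odd moments, which would make B₃'s relative variation meaningless).
  The invariants are computed on the native-space PTV rather than the rigidly
  resampled one: they are invariant to that alignment by construction, and
  skipping the resampling avoids injecting rasterisation error into the shape
  descriptors.
- **Head–foot features.** PTV z-extents use full voxel coverage (half a voxel
  beyond the extreme voxel centres); P_ovz is the Dice-style overlap of the
  two z-intervals. The head–foot axis is singled out because collimation
  blocks most out-of-field dose in that direction, making longitudinal
  alignment disproportionately predictive.
- **Image MSD** is computed over the full common grid (no subregion), after
  rigid alignment.

## Comprehensive score

The score model is a scikit-learn style transformer fitted on a table of
feature vectors (one row per ordered atlas pair):

1. z-standardise each feature with the fitting-table mean/SD (PCA-based
   extraction needs a scale convention; the raw features mix units from cGy²
   to dimensionless),
2. eigendecompose the correlation matrix; retain factors with eigenvalue > 1
   (Kaiser criterion, on the *unrotated* eigenvalues),
3. varimax-rotate the retained principal-component loadings,
4. factor scores for new pairs via the Thomson regression method,
   `scores = Z R⁻¹ L` (pseudo-inverse, so small fitting tables stay usable),
5. comprehensive score `F = Σ λᵢ Fᵢ / Σ λᵢ` with λᵢ the rotated explained
   variances (sums of squared rotated loadings).

Fitting is gated on KMO > 0.5 and Bartlett sphericity p < 0.05 (both
implemented from their standard definitions); `enforce_gates=False` records
the diagnostics without failing, which is appropriate for small demonstration
cohorts where the correlation matrix is noisy or singular. The Spearman screen
(`spearman_screen`) retains a feature if it correlates significantly (p < 0.05,
either sign) with at least one of the nine dose-error outcomes; constant
columns are dropped with a warning since their rank correlation is undefined.

Selection polarity: features shrink with similarity, so the *minimum* F marks
the most similar atlas, and the weight rescaling maps F_min → weight maximum.
The opposite convention is switchable (`AtlasDosePredictor(select="max")`)
for sensitivity analysis.

Degenerate fusion cases: all-equal scores make the min-max rescaling 0/0 and
fall back to uniform weights with a warning; a single-atlas database makes
every strategy return that atlas's warped dose unchanged.

For SIM, only the selected atlas receives the deformable stages (selection
needs only rigid alignment, and deforming every atlas just to discard all but
one would triple the cost); for WEI, every atlas is deformably registered, and
WEI_A/WEI_F can share one registration pass through the predictor's
`warp_atlas_doses` cache.

## Evaluation

- **MAD** is the mean absolute voxel dose difference over an ROI (cGy).
- **Isodose Dice** thresholds both dose grids at 80% / 100% of prescription.
- **Gamma** uses global normalisation (Δd as % of the 5000 cGy prescription)
  and is evaluated at reference voxels with dose ≥ 80% of prescription. The
  search minimises over the predicted dose trilinearly refined 3× per axis
  (configurable) within a window of 2·Δr per axis. The window cap is exact for
  the pass rate: any candidate farther than Δr fails on the spatial term
  alone, so capping at ≥ 1·Δr cannot change whether γ ≤ 1. The implementation
  is tested to agree with a full-volume exhaustive search to 1e-12.
- **Statistics.** Friedman across ≥ 3 methods per metric; if rejected at 0.05,
  pairwise Wilcoxon signed-rank post-hocs with exact p-values for n ≤ 25 and
  the normal approximation above. All-identical method columns short-circuit
  to p = 1 (the tie-corrected Friedman statistic is 0/0 there).

## Synthetic phantoms

`dosecast.phantom` generates left-breast-like cases: an elliptic-cylinder
trunk with a left-anterior breast bulge (the CTV), two lung ellipsoids, a
heart, a posterior cord and vertebral column, CT-like intensity bands with
Gaussian noise, PTV = CTV + 10 mm margin clipped 5 mm inside the skin, and an
analytic dose: prescription (±2% smooth noise) in the PTV, Gaussian falloff
with signed distance outside (σ = 12 mm, putting the 80% isodose ≈ 5–6 mm
outside the PTV, a plausible VMAT penumbra), a tangential low-dose corridor
(15% of prescription) through the ipsilateral lung at the PTV's head–foot
position, and a weak ambient scatter tail (3% of prescription, 120 mm decay)
so distant organs see a small, nearly flat dose. Cohorts draw per-case
anatomy (breast size ±~25%, body/lung/heart ±~8%, bulge position and angle)
from a seeded generator; the default ranges put 20-case PTV volumes in
roughly 310–1100 cm³ with a mean near 650 cm³, matching the spread reported
for clinical breast cohorts. A `near_twin` mode plants a mildly perturbed
clone of a test case in the atlas for retrieval tests.

What the phantoms deliberately do **not** model: beam/arc geometry and dose
physics (no beam's-eye-view effects, no buildup, no heterogeneity
corrections), inter-observer contouring variation, couch/positioning
differences, and realistic CT texture. Passing tests therefore demonstrate
that the pipeline's geometry, scoring, fusion and evaluation machinery behave
correctly and that similarity-weighted fusion exploits anatomical similarity;
they do not certify clinical accuracy on patient data, which requires the
kind of private planned cohort the method was designed for.

## Problem sizes and numerical choices

Default phantom grids are 96×96×64 at 3 mm. The test suite and the acceptance
script run cohorts at 64×64×44 with 4.5 mm spacing — the same 288 mm
transaxial field of view at coarser sampling — which keeps a full
registration chain at a few seconds and a 10-atlas/5-test experiment around
five minutes on one CPU while preserving every qualitative behaviour the
tests assert. Other numerics: grids compared with 1e-4 mm tolerance; masks
resampled nearest-neighbour (binary in = binary out); varimax iterated to
1e-10 relative criterion change; factor signs fixed so each column's loading
sum is positive (rotation is sign-ambiguous); rotated factors ordered by
explained variance.

## Known limitations

- Demons here is the additive (non-diffeomorphic) variant; extreme anatomy
  differences can fold the displacement field. The non-worsening guards bound
  the damage but do not prevent local folding.
- The PTV-constraint stage optimises PTV overlap only; it can degrade
  alignment far from the target. This mirrors the design intent (high-dose
  accuracy first) but is a real trade-off for distant OARs.
- The comprehensive score is fitted on ordered-pair feature tables; with few
  atlases the correlation matrix is near-singular and the factor solution
  unstable (hence the pseudo-inverse scoring and the optional gates).
- Gamma is computed on the reference voxel lattice with interpolation of the
  *predicted* dose only; the reference is not interpolated between centres.
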