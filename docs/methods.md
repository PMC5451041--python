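# Methods

## Model overview

The package simulates a four-arm attenuation-correction (AC) comparison
on a synthetic axial thorax.  One emission data set per subject is
generated with the *true* attenuation (the continuous CT-derived μ-map)
and reconstructed four times; only the AC μ-map changes between arms.
Because every arm shares the same counts, per-ROI relative differences
between arms are nearly noise-free, which is what makes a small synthetic
cohort informative.

## Digital thorax phantom

Geometry (defaults, mm): body ellipse 320 × 230 with a 12 mm subcutaneous
fat ring; two lung ellipses 96 × 150, centres ±55 laterally and 8 mm
anterior of the grid centre; a 20 mm-radius spine cylinder centred 78 mm
posterior; four rib circles (5 mm radius) per side on the
lateral-posterior arc.  Grid: 256 × 256 voxels at 2.6 mm isotropic, one
axial slice by default (multi-slice volumes replicate the section with
independent noise).  The geometry is symmetric about the mid-column, so a
noise-free phantom is exactly mirror-symmetric — the basis of the
left-right equivalence checks.

Lung HU follow a continuous piecewise-linear profile of the depth
fraction f ∈ [0, 1] over each lung's anterior-posterior extent, split
into three equal bands.  Band slopes are solved so each band *mean*
equals its target (−779 / −746 / −685 HU) exactly; the residual
discretisation error (the ellipse narrows with depth, so rows are
unevenly populated) is removed by a per-band mean-centring offset of
≈ 1–2 HU.  The anterior-minus-posterior band difference is therefore
exactly −94 HU at zero noise.  Other tissues are constant: soft 40, fat
−90, bone +700 HU.  Gaussian voxel noise (default SD 20 HU, a typical
chest-CT noise level at this voxel size) is added inside the body only.

Activity is uniform per tissue class, specified as the SUV the class
should read (lung 0.4, soft 1.0, fat 0.3, bone 0.5) and converted to
Bq/mL with the configured dose (350 MBq) and weight (70 kg).  A uniform
lung means any reconstructed anterior-posterior SUV gradient is
attributable to AC alone; an optional `activity_gradient` parameter can
emulate genuinely higher posterior uptake, and is off by default.

## HU → LAC transform

Two-segment map anchored at μ(−1000 HU) = 0 with below-break slope
9.6 × 10⁻⁵ cm⁻¹/HU (water scaling: μ(0 HU) = 0.096 cm⁻¹), break at
47 HU and above-break slope 5.1 × 10⁻⁵ cm⁻¹/HU — the standard 120 kVp
PET/CT parameterisation.  The above-break intercept is derived from
continuity at the break rather than stored as an independent rounded
constant, so the transform is continuous to machine precision; all four
parameters are configurable.

## μ-map variants

* Lung masks are region-grown (face connectivity, threshold −300 HU)
  from one seed per lung at the true lung centroid, standing in for the
  operator's seed click; on label-consistent phantoms the grown mask
  equals the true labels.
* Lung replacement writes the fixed class LAC 0.0224 cm⁻¹ into the mask.
  At the default HU targets the continuous lung LAC crosses the class
  value near −766 HU, so replacement raises μ anteriorly (−779 HU →
  0.0212 cm⁻¹) and lowers it posteriorly (−685 HU → 0.0302 cm⁻¹).
* Bone stripping sets LAC > 0.10 cm⁻¹ (strictly greater) to the soft
  class value 0.1 cm⁻¹.  With CT noise a few dense soft-tissue voxels
  also cross the threshold, as they would on real data.
* The 4-class map assigns air/lung/fat/soft values from the labels, with
  bone deliberately mapped to soft tissue.
* QC: the voxelwise difference between the fully edited CT map and the
  class map is histogrammed inside the body; the reported metric is the
  fraction of voxels within 10% of the soft LAC.  On the intrinsically
  aligned phantom this fraction is ≈ 1 by construction; on real data it
  measures registration quality.

## Projection, simulation, reconstruction

2-D parallel-beam geometry: 168 angles over [0, π) (divisible by the 21
subsets), 256 bins as wide as a voxel.  The projector is an explicit
sparse matrix per angle, built by sampling each LOR every half voxel with
bilinear interpolation; backprojection is the exact transpose, so the
adjoint identity holds to floating point and EM fixed points are
well-defined.  A single 3-D scanner reconstruction is replaced by this
transparent in-plane model deliberately: the density-gradient and bone
effects are in-plane phenomena, and a matched projector pair makes every
claim testable against closed forms (chord lengths, exp(−∫μ), scale
equivariance).

Emission: expected counts = count_scale · (forward-projected activity) ·
(survival factors of the true μ-map), Poisson-sampled, with the expected
total fixed at 10⁷ counts per slice — a realistic event count for a
2.6 mm thorax slice, chosen so the nonnegativity (low-count) bias of EM
in the cold lung stays well below the AC effects under study.  Scatter,
randoms, normalisation and time-of-flight are not modelled.

OSEM: multiplicative updates with the AC factors in the per-subset
sensitivity, angle-interleaved subsets, uniform positive initialisation,
2 iterations × 21 subsets, then one 4 mm-FWHM Gaussian filter in image
space.  Division guards use a 10⁻¹² floor; zero-sensitivity voxels are
pinned at zero.  SUV scaling divides by the recorded count calibration
and by dose/weight.

## Regional analysis

Twelve 1 cm ROIs per subject: per lung, anterior/middle/posterior centred
at 20/50/80% of that lung's anterior-posterior extent, at a "hilum" and a
"basal" axial level (the same slice twice on single-slice phantoms — the
scheme's pooling, not extra information).  ROI centres start at the
lung's mid-column at the target depth and are nudged laterally until the
full 5 mm radius fits inside the mask.  Statistics pool sides, levels and
subjects per depth position.  Relative differences are computed per ROI
against the CTAC reading and then averaged — not as differences of
regional means.  Group contrasts use one-way ANOVA plus pairwise t-tests
with Bonferroni multiplication (capped at 1); degenerate inputs resolve
to the test's limit (identical data → p = 1; zero within-group variance
with unequal means → p = 0).

The emphysema screen splits each lung into three equal-extent segments —
cranio-caudally when ≥ 3 slices exist, otherwise along the in-plane
anterior-posterior axis as a surrogate — and flags a segment iff its mean
HU is strictly below −950.

## Cohort and reproducibility

Subjects are i.i.d. phantom draws: per-subject seeds from a spawned
`SeedSequence`, fresh HU noise, and a 2%-SD uniform scale jitter of the
anatomy.  This emulates scan-to-scan variability only; the reported SDs
are pooled-ROI SDs of synthetic repeats and are not comparable to
inter-patient SDs of a clinical cohort.  Reports carry a config hash and
the seed schedule; identical config + seed reproduces every number
bit-identically.

## What the synthetic cohort does and does not show

The phantom reproduces the mechanism — band-calibrated lung density
gradient, posterior bone, class-based μ-maps — so the *signs and
orderings* of the regional biases (anterior overestimation, posterior
underestimation, deeper posterior underestimation after bone stripping,
class map ≈ fully edited CT map, monotone weakening of the
anterior-posterior SUV gradient across arms) are the meaningful outputs.
Magnitudes are not transferable to patients: real lungs have continuous
heterogeneous density rather than three exact bands, true uptake is not
uniform, the scanner is 3-D with scatter and coil attenuation, and the
reference arm in a patient study carries its own errors.  The null
control (class-matched tissue, no gradient, no bone) verifies that the
pipeline itself contributes no regional bias: all four arms then agree
exactly.

## Numerical choices and limitations

* Ray sampling at half-voxel steps balances accuracy (closed-form chord
  integrals to ≈ 0.3%) against the sparse-matrix footprint (≈ 1.5 GB at
  the 256/168 default, built once per geometry and cached).
* 2 OSEM iterations are far from convergence by design (clinical
  protocol); recovery oracles use 10+ iterations without the filter.
* Single-slice phantoms make the two ROI levels coincide; multi-slice
  mode removes this but multiplies runtime by the slice count.
* Default problem sizes (five subjects, one 256² slice, 10⁷ counts) keep
  a full cohort run under a minute on one CPU while leaving the pooled
  orderings stable across seeds.
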