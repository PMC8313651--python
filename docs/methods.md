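# Methods

This note documents the models and numerical choices behind `regqa`, module
by module, including the points where the procedure was genuinely open and a
design decision had to be made.

## Landmark score D (`regqa.landmarks`)

The score is a weighted sum over 25 bronchial landmarks. Weights (16 trachea,
7 per main bronchus, 3 per lobar bronchus, 1 per segmental bronchus; total
62) are roughly proportional to bronchial cross-section, encoding that a
usable registration must get the large structures right. Reference diameters
are 18 mm (trachea) and 12.2 mm (main bronchi), giving the 10%/20% distance
thresholds 1.8/3.6 mm and 1.22/2.44 mm.

*Boundary handling.* The three distance classes are made disjoint with a
closed upper bound on each: d ≤ 10% → 1, 10% < d ≤ 20% → ½, d > 20% → 0.
No measurement in the reference cohort falls exactly on a boundary, so this
choice is not observable there, but it preserves the "≤ 10%" rule for the
1-class.

*Missingness.* NA (not identifiable in the ldCT) and NULL (absent or obscured
in the hdCT) are semantically different and are preserved through I/O, but
both contribute 0 to D. The reference score table prints missing cells
inconsistently (NA in some cells, 0 in others); outputs here always print NA
for missing, and the totals are unaffected.

Weights and diameters are configuration (a `Landmark` mapping) with the
reference values as immutable defaults, since other cohorts may rescale them.

## Similarity parameters (`regqa.similarity`)

All histogram-based quantities derive from one joint histogram: equal-width
bins (default 64 per image) spanning each image's [min, max] over the mask,
top edge inclusive, constant images collapsing to a single occupied bin. The
bin count is configurable because the absolute MI scale depends on it; the
default of 64 is a common registration choice. Logarithms are natural, so
MI/NMI/HKL are in nats.

* Pearson r uses the raw masked intensities, not the histogram. A constant
  image on the mask raises `DegenerateInputError` rather than returning a
  silent value.
* NMI is (H(A)+H(B))/H(A,B), bounded in [1, 2] (the reference cohort's NMI
  values of 1.04–1.21 are consistent with this definition and rule out
  variants bounded by 1).
* HKL is the directed KL divergence of the reference image's marginal
  histogram from the moving image's, over bins where the reference marginal
  is positive, with empty moving bins floored at ε = 1e−12. The operands of
  the divergence were not fully specified in the source procedure; the
  marginal-vs-marginal form is an assumption, documented here, chosen because
  it behaves as a dissimilarity (larger = worse) on misregistered pairs.
* L1norm and L2norm2 are plain sums over masked voxels, so their magnitude
  scales with mask size (order 1e7/1e10 on full-size lung-masked CT pairs,
  matching the 1e−7/1e−10 column scaling of the reference cohort table).

Masking modes: α uses every voxel; β uses a single functioning lung-mask
derived from the reference (hdCT) volume and applied to both images; γ uses
the union of the two per-image 10-mm-extended airway masks. The union (rather
than intersection) is symmetric in the two images and never empty when either
airway was found.

## Masks (`regqa.masks`)

The raw lung mask is the HU window [−1000, −400] minus every connected
component touching a lateral face of the volume (exterior air) and minus
components below `min_component_voxels` (default 64; noise specks).
Connectivity is 26-neighbourhood.

The functioning lung-mask must make mask-driven registration robust, which
the source procedure describes by goal ("eliminate major discontinuities, add
the mediastinum") rather than by operator. Implementation: morphological
closing with a mm-radius ball (default 5 mm, anisotropy-aware, computed on a
padded array so the closing is not clipped at borders), 3-D hole filling,
then per-axial-slice convex hull, which bridges the gap between the two lung
fields and thereby adds the mediastinum. The hull step is iterated to a fixed
point per slice (the discrete convex hull of a lattice set is not always
stable after one pass), which makes the whole operation idempotent and every
step extensive (output ⊇ input). The per-slice convex hull is an
approximation of the anatomical mediastinum: it also includes some anterior
and posterior non-lung tissue, which is acceptable for a registration support
mask.

The extended airway mask thresholds the anisotropy-aware Euclidean distance
transform of the airway complement at `extension_mm` (default 10), so the
extension is exact in millimetres regardless of voxel shape.

## Airway tree (`regqa.airway`)

*Region growing* is a fixed-interval criterion: the maximal 26-connected
component containing the seed whose voxels all lie in the homogeneity
interval (default [−1024, −950] HU for lumen air). The original segmentation
tool iterates its homogeneity criterion adaptively, but that update rule is
unpublished; the fixed interval reproduces the documented interface (seed +
criterion) and is exact on phantoms.

*Skeleton.* One node per in-plane 8-connected component per axial slice, at
the component's centre of gravity in world mm, stored as
`(i, x, y, z, i1, i2, …)` text records. Cross-slice linking uses in-plane
voxel overlap (robust for curved tubes, unlike centroid distance); a
component overlapping several on the next slice becomes a branching node.
When a component overlaps several components of the previous slice (a merge,
impossible in a tree), it attaches to the largest-overlap parent. The root is
on the most cranial non-empty slice; if that slice has several components the
largest is taken with a warning, and islands unreachable from the root are
dropped with a warning.

*Pruning* erases terminal chains (leaf up to the nearest branching node,
exclusive) with fewer than 6 nodes, iterated to a fixed point. A short twig
that itself branches before its sixth node is, under this chain definition,
not a single terminal chain, so its stem survives — only its short terminal
sub-chains are erased. A chain containing the root is never erased, so the
tree cannot be emptied; this degenerate case (whole airway shorter than six
slices) is not covered by the source procedure.

*Surface and projection.* Surface elements are airway voxels 6-adjacent to
the outside; normals are the normalised gradient of a Gaussian-smoothed
(1 mm) signed distance field, pointing outward. Activity is projected
perpendicularly: per element, trilinear samples along the outward normal at
steps of half the minimum spacing, out to `depth_mm` (default 10 mm, the
range of a transbronchial needle), keeping only samples outside the airway,
summed. An alternative `method="shell"` aggregates every outside voxel within
`depth_mm` of the airway onto its nearest surface element; the ray method is
the default because it honours perpendicularity, the shell method the
literal 10-mm-neighbourhood reading.

## Statistics and decision model (`regqa.stats`)

Correlation of D with a similarity parameter is plain Pearson r with the
t-test p-value (n−2 d.f.) and a Fisher-z CI (z ± z₀.₉₇₅/√(n−3),
back-transformed). The reference analysis used a linear-model fit; plain
Pearson reproduces its printed correlation and CI to printed precision, so
nothing more elaborate is warranted.

The cohort split takes the `n_insufficient` lowest-score records (default 7,
which on the reference cohort is equivalent to score < 52 and reproduces the
printed subset means 0.19/0.324); ties break by row order, deterministically.
The bootstrap statistic is the subset mean: resample with replacement at the
original size, 10,000 times (configurable, ≥ 1000 enforced), percentile
interval at 95% (2.5% trimmed per tail), bias = mean of bootstrap means −
sample mean. Randomness comes from `numpy.random.default_rng`; `calibrate`
derives two independent child seeds from the user seed via `SeedSequence`,
so a `DecisionModel` is bit-reproducible from (cohort, seed).

Calibration fails loudly (`CalibrationError`) if the two intervals overlap,
since the decision rule presumes separation. Classification is monotone:
values at or above the accept interval's lower bound are accepted, at or
below the reject interval's upper bound rejected, and the gap means repeat.
Extending the accept region above its interval (and reject below) is an
extrapolation by monotonicity — a higher similarity is never worse — and is
deliberate rather than silent.

## Phantom generator (`regqa.phantom`)

The phantom exists to give every operator a ground truth: HU layering (air
−1000, body 40, lung −850, lumen −1000, bone 700), two lung ellipsoids, a
posterior spine rod, and a binary airway tree of capped cylinders rasterised
in world mm (trachea 36 mm long, 4 mm radius, branch angle 40°, length/radius
decay 0.65/0.7, default depth 1 — a single carina). Default grid 48×56×56 at
2.0×1.5×1.5 mm (a realistic thorax-CT anisotropy at reduced matrix size;
tests use this or smaller grids so the full suite runs in seconds). Noise is
additive Gaussian in HU (`noise_sd`, default 0 so ground-truth recovery is
exact). Misregistration applies a known rigid translation/rotation by
trilinear resampling; low-dose emulation is 1.5 mm Gaussian smoothing plus
doubled noise. All randomness is seeded; identical specs give bit-identical
volumes.

What the phantom does *not* emulate: real anatomy (lobar structure,
vasculature, diaphragm), scanner physics (beam hardening, dose-dependent
noise texture, reconstruction kernels), breathing-state differences, and
non-rigid misregistration. Tests passing on phantoms therefore demonstrate
algorithmic correctness (exact segmentation recovery, metric oracle
equivalence, monotone MI degradation under displacement), not clinical
performance; the clinical numbers in the package all come from the packaged
expert-scored cohort tables.

The landmark-cohort generator draws, per patient with latent misalignment m
(mm), large-airway distances from m·Lognormal(0, 0.4) (median m, exactly 0
at m = 0) and in-lumen indicators from Bernoulli(exp(−m/2.5)); NA and NULL
are injected at 3%/2% by default (the reference table carries ≈ 4.5%
missingness). The latent quality label exp(−m/3) lets tests verify that D
tracks true registration quality.

## Problem sizes

Unit and property tests run on grids up to 56×72×72; the MI-degradation
check uses 10 seeds × 4 displacements on a 40×48×48 grid with all three
masking modes. The bootstrap uses the full 10,000 resamples everywhere. The
complete test suite runs in a few seconds on one CPU.

## Known limitations

* Absolute MI/NMI/HKL values depend on the bin count; cross-study comparison
  requires fixing `n_bins` (as the decision-model calibration itself does).
* The mediastinum bridge is a per-slice convex hull, not an anatomical
  mediastinum; it over-includes anterior/posterior tissue.
* The skeleton is slice-wise, so airway segments running nearly parallel to
  the axial plane are represented coarsely.
* The decision model is calibration-specific: any change in scanner,
  segmentation or registration protocol invalidates the intervals and
  requires recalibration on a newly scored cohort.
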