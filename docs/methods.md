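# Methods

## Scope and model

The package links two descriptions of the same tumor: a radiomic one (51
features of the 3D CT region of interest, per channel) and a pathologic one
(the mixture of IASLC/ATS/ERS growth patterns from comprehensive histologic
subtyping).  The pathologic side is deterministic given a composition: the
heterogeneity index is the weighted mean `H = Σ w_s p_s / 100` of subtype
proportions, with non-negative weights meant to be derived from
disease-free-survival hazard ratios.  Published hazard-ratio sets vary by
cohort, so the shipped default weights encode only the uncontroversial
aggressiveness ordering — lepidic 0, acinar 1, papillary 1, micropapillary 2,
solid 2 — and are plain configuration; substituting any published set changes
nothing structural.  Proportions are kept on the nearest-5% grid summing to
100 (largest-remainder repair), matching how comprehensive subtyping is
reported; fibrosis may be recorded but sits outside the subtype simplex.

## Image handling and quantization

Volumes are read from NIfTI (nibabel) or NRRD (SimpleITK) with header
spacing in mm, axes fixed to (x, y, z) at read time, values assumed already
in HU.  Masks must live on the image grid — there is deliberately no
resampling or registration stage — and every computation is mask-strict:
background voxels are excluded, never zero-filled.

Two quantization profiles feed the features:

* **texture profile** — 16 equal-width levels over a fixed window of
  [−1000, 400] HU, used for the co-occurrence and size-zone matrices.  A
  fixed window makes a level mean the same attenuation band in every tumor,
  so a tumor mixing ground-glass and solid compartments genuinely occupies
  more levels than a homogeneous one.  (Binning each ROI over its own
  observed range instead makes added compartments *coarsen* the
  within-compartment binning and suppresses exactly the mixing signal the
  analysis is after; that variant remains available by setting
  `texture_range: null`.)
* **histogram profile** — 256 bins over the same window, used for the
  regional uniformity/entropy statistics, whose published magnitudes
  (entropy ≈ 9 bits) imply fine binning.

The `quantize` operation itself defaults to the observed ROI range when no
window is passed, erroring on constant ROIs; the profiles above are how the
pipeline calls it.

## Feature definitions and conventions

Physical: volume `N·dx·dy·dz/1000` cm³; density the per-voxel
`max(0, (HU+1000)/1000)` averaged over the ROI (the standard CT mass
convention; the floor only matters for sub-air artifacts); mass =
volume × density; size the largest in-plane (axial) pairwise distance
between foreground voxel centers, matching clinical practice (a 3D diameter
sits behind `size_3d`).

Histogram: central moments with 1/N; kurtosis non-excess (normal = 3);
percentiles by linear interpolation.  Zero-variance ROIs report
skewness/kurtosis as missing rather than raising.

Local texture: one co-occurrence matrix per direction (13 canonical
non-collinear 3D neighbors) per distance d ∈ {1, 2, 3} voxels along the
offset — voxel units, spacing ignored, per the distance definition in voxel
steps.  Matrices are symmetrized and normalized; masked-out endpoints drop
the pair.  Feature conventions worth naming: entropy is log₂ throughout;
*contrast* is the first difference moment `Σ|i−j|p` while *inertia* is the
second `Σ(i−j)²p` (the classical Haralick contrast), keeping the two
reported columns distinct; homogeneity is computed on probabilities and
hence lies in (0, 1]; correlation uses the symmetric-marginal form and is
missing when only one level is occupied.  The per-distance value is the
unweighted mean over directions that produced at least one pair, and the
count of contributing directions is recorded.

Regional: zones are maximal 26-connected (configurable to 6) equal-level
components of the texture-quantized ROI; gray-level and zone-size
non-uniformity are each normalized by the zone count, so both equal 1 when
all zones are alike.  Uniformity and entropy are first-order statistics of
the fine histogram — their published magnitudes fit fine-binned histograms,
not zone matrices, and they are documented as such.

## Statistics

Spearman's rho uses average ranks; its p-value is the exhaustive two-sided
permutation tail for n ≤ 9 and the t approximation beyond.  Strength bands
on |rho|: [0, 0.2) very weak, then weak, moderate, strong, and very strong
from 0.8 (the published band wording ends "greater than 0.80, strong",
an evident duplication of the 0.60–0.79 label; it is read as "very
strong").  Lin's CCC uses population (1/n) moments; an identical constant
pair is perfect agreement (1), any other zero-variance pair is 0.  ANOVA is
one-way fixed-effects with Tukey HSD, Tukey–Kramer under unequal n
(scipy's studentized-range implementation).  No multiple-testing correction
is applied anywhere, matching the source analysis; reports carry raw
p-values only.

Model selection is bidirectional stepwise search on a Gaussian linear model
scored by AIC, from the intercept-only model, taking the single best
add/drop per step, ties broken by column order, stopping at a local
minimum.  The published description says "multivariate logistic regression",
but the target is continuous and the validation statistic is a Pearson
correlation of predictions with the index, which is only coherent for the
Gaussian reading; the Gaussian path is therefore primary (dichotomizing the
index for a logistic variant is a one-liner on top of the returned design).
Known property, stated rather than hidden: AIC's penalty admits noise
variables at ≈ 16% per candidate under the null, so a selected set typically
contains a spurious term or two alongside genuine signal; the calibration
checks therefore assert recovery (selected ⊇ planted set), not purity.
Cross-validation shuffles once per seed into k = 10 near-equal folds and
re-runs the entire selection inside every training split; both the in-fold
(full-data fitted) and out-of-fold Pearson r are reported.  Under a
pure-noise target the out-of-fold r is not centered at zero but slightly
negative (median ≈ −0.05 to −0.10 at n = 100 with 8 candidates): training
folds fit noise, and those fits anti-predict held-out data.  The
calibration suite bounds |median r| at 0.1 with that documented simulation.

## Phantom generator

One phantom = ellipsoidal mask (semi-axes 0.42 × grid, default grid
28×28×14 at (0.7, 0.7, 1.0) mm — a ~2 cm tumor kept small enough that a
full cohort extracts in seconds) partitioned into one compartment per
subtype present.  Compartments grow around seeded interior points by
nearest-seed assignment under volume quotas (largest-remainder integer
quotas, largest compartment first), a capacity-constrained Voronoi
partition giving contiguous irregular regions whose realized fractions
match the composition to well within 5 percentage points.  Voxels draw from
their subtype's HU normal — lepidic (−650, 80), acinar (−300, 90),
papillary (−150, 90), micropapillary (−50, 80), solid (30, 60), the
ground-glass → solid spectrum — plus global N(0, 20 HU) noise, a typical
thin-section noise scale; the iodine channel draws analogously from
enhancement distributions ordered by expected vascularity (5 → 45 HU,
SD 15).  Outside the mask the non-contrast channel is air (−1000) and the
iodine channel 0.

Compositions: subtype combinations are drawn with the frequencies of the
published 89-tumor cohort pattern table (lepidic+acinar dominating the
two-subtype class, 19/54/14/2 across subtype counts), proportions from a
flat Dirichlet, rounded to the 5% grid with every chosen subtype kept
strictly positive.  Cohorts additionally scale each tumor's grid by a
uniform factor in [0.75, 1.5], since constant tumor size would make volume,
size and mass degenerate across the cohort (undefined correlations, zero
between-tumor variance in the stability analysis).

What the phantoms do *not* emulate: CT physics (beam hardening, kernels,
partial volume), lesion-shape irregularity, spatial intra-compartment
correlation (voxels are independent draws), and any survival linkage behind
the index weights.  Passing the end-to-end checks therefore demonstrates
that the pipeline recovers the directions a compartment-mixture model
implies, not that it reproduces patient-cohort effect sizes.

With these conditions the synthetic cohort reproduces the published
qualitative structure: density and the upper HU percentiles correlate
strongly with the index (the aggressive patterns are the dense ones);
regional entropy, local co-occurrence entropy and inertia escalate — and
homogeneity declines — with the number of mixed subtypes; and the local
entropy-vs-index correlation stays weak, because the equally-weighted
aggressive mixtures produce less image contrast than the lepidic-containing
ones.  The inter-reader stability simulation perturbs reader A's mask by a
one-voxel erosion (staying inside tumor tissue, as a second reader would)
and yields mean CCC ≈ 0.95.

## Numerical and degenerate-input choices

Quantization clips into the window, top bin right-closed; level maps are
bit-reproducible and shift-invariant when the window shifts with the data.
Single-voxel ROIs yield physical features but missing texture (no pairs,
logged, never zeroed).  Ties in predominance go to the more aggressive
subtype (solid > micropapillary > papillary > acinar > lepidic).  Tumor
compositions that round to an empty simplex re-apportion from raw shares;
all-zero input is an error.  Every pipeline report embeds the serialized
run configuration as a `#` header line, and byte-identical re-runs under a
fixed seed are asserted in the suite (NIfTI outputs are written
uncompressed so no archive timestamps enter the bytes).

## Problem sizes used by the checks

Oracle equivalence uses 200 random arrays up to 6³ against double-loop and
flood-fill references; statistical calibration uses 100 replicate seeds for
signal recovery (n = 200, 2 planted + 8 noise features) and the null CV
(n = 100, 8 candidates); the end-to-end pass uses a 150-phantom cohort and
25 mask pairs for stability.
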