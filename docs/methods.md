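# Methods

This note documents the models, numerical conventions and design choices
behind `raterlab`, and what its synthetic-cohort tests do and do not show
about real reader studies.

## Data model and conventions

All volumes live in a canonical axis order `(x, y, z)` with the third axis
cranio-caudal; the slice index increases from the apex (caudal) to the base
(cranial). NIfTI files are reoriented to nibabel's closest canonical (RAS)
frame on read. NRRD/MetaImage direction matrices must be axis-aligned
(signed permutations); they are undone so the third array axis points
cranially, and oblique matrices are rejected — resampling is out of scope.
A caveat follows: a clinical LPS-frame file and a RAS NIfTI may end up with
opposite in-plane handedness; only the cranio-caudal axis semantics, which
the regional analysis depends on, are guaranteed consistent across formats.
Indexing is 0-based; slice ranges are half-open `[lo, hi)`.

Label files are binarized nonzero → 1 (with a warning when several distinct
nonzero labels are present), tolerating exporter dialects. The peripheral
zone is derived as `PZ = WG ∖ TZ`, with the central zone folded into the PZ
and the anterior fibromuscular stroma into the TZ; strict nesting of TZ in
WG is enforced (configurable tolerance, default 0).

## Overlap and surface metrics

A voxel is a *boundary* voxel if it is foreground with at least one
background 6-neighbour (out-of-array counts as background). Surface
distances are computed with exact Euclidean distance transforms, cropped to
the union bounding box plus one voxel (an exact optimisation), and are
validated in the tests against brute-force all-pairs oracles.

Choices worth making explicit, because reader-study reports rarely state
them:

- **HD** is the exact (100th-percentile) Hausdorff distance by default;
  HD95-style percentiles are an option.
- **AHD** is the *maximum* of the two directed mean boundary distances,
  the convention of the widely used VISCERAL EvaluateSegmentation tool;
  the symmetric-mean variant is available via `variant="mean"`.
- **"voxel" units** mean Euclidean distance on integer index coordinates,
  ignoring spacing even on anisotropic grids — the convention in which
  clinical HD tables in voxels are reported. `units="mm"` scales each axis
  by its spacing.
- **Distance support** defaults to boundary voxels; `distance_support="all"`
  measures from every foreground voxel instead, preserving the alternative
  reading.
- **Slicewise (2D) metrics** average per-axial-slice values: slices where
  both masks are empty are excluded; slices where exactly one is empty
  contribute DSC 0 and are excluded for HD; an error is raised when no
  slice has both masks nonempty.

DSC on two empty masks is undefined and raised as a distinct error, never
silently scored.

## STAPLE consensus

Binary STAPLE estimates a voxelwise posterior `W_i = P(T_i = 1 | D)`
jointly with per-rater sensitivity `p_j` and specificity `q_j` by EM, under
a spatially constant foreground prior `f`. Numerical choices:

- initialisation `p_j = q_j = 0.99999` (the reference algorithm's classic
  practice);
- prior `f` = mean foreground fraction across raters ("sample-mean"),
  computed inside the working region; a constant in (0, 1) can be supplied;
- the computation is restricted to the bounding box of the union of rater
  masks dilated by 10 voxels (configurable). A global background prior over
  a full field of view would swamp `f` and degrade the performance
  estimates; restricting the region is a deliberate, documented deviation
  risk relative to running EM on the whole grid;
- convergence when the largest change in any `(p_j, q_j)` drops below
  `1e-7`, at most 100 iterations; non-convergence returns a result flagged
  `converged=False` with a warning rather than an error;
- the consensus mask thresholds the posterior at 0.5, with ties counting as
  foreground for determinism.

On synthetic cases the consensus mask agrees with SimpleITK's independent
STAPLE implementation to DSC ≥ 0.99 (exact numeric parity with that
implementation's unspecified internals is not promised and not needed).

## Regional decomposition

The comparison extent along the slice axis is the span of
foreground-containing slices of the *union* of the compared pair (pairwise
frame) or of the consensus mask (STAPLE frame). The union is chosen for the
pair because it keeps the regional metric symmetric in the two raters; the
intersection alternative is available. An extent of `L` slices splits into
`floor(L/3)` (apex) / `L − 2·floor(L/3)` (mid) / `floor(L/3)` (base), the
remainder going to the mid-gland so the two extreme regions stay
equal-sized. Base is the most cranial third.

Empty-region policy: a region where both sub-masks are empty is skipped
with a log line; where exactly one is empty, DSC is 0 and distance metrics
are skipped. The three regional sub-masks tile the original mask exactly
within the extent (asserted by tests), so whole-gland intersections equal
the sum of regional intersections there.

## Morphology covariates

The ellipsoid volume `V = length × width × height × 0.52` takes dimensions
in cm, normally user- or generator-supplied; a convenience derives them
from a mask's bounding-box diameters (a deliberate stand-in for
caliper-style measurements, accurate to ~15% on ellipsoids at coarse
grids). Both the mean and the median of the per-rater volumes are reported:
the two natural summaries differ in general and both appear in clinical
reporting practice, so the package computes both and uses the mean as the
default covariate.

Zonal signal intensities are mean values over spherical ROIs (default
radius 3 mm, in physical space — a sphere because "similar sized ROIs" is
orientation-free); in the pipeline the ROIs sit at the deepest interior
points (distance-transform argmax) of the true TZ and PZ. The squared
contrast `((SI_TZ − SI_PZ)/(SI_TZ + SI_PZ))²` is symmetric and
scale-invariant.

## Synthetic cohort generator

The generator emulates the *statistical structure* of a seven-reader
prostate study, not prostate MRI appearance:

- **anatomy**: WG is an ellipsoidal blob (semi-axis ratios 1 : 0.88 : 1.12)
  with a smooth multiplicative radial perturbation (4% RMS, 8 mm
  correlation length); TZ is a concentric nested blob at a sampled volume
  fraction (default range 0.25–0.55). Volumes are log-uniform over
  15–199 cm³, the clinical range. Realized voxel volumes land within ~5% of
  target;
- **intensity**: two-level zonal signal (PZ 400, TZ set from the target
  squared contrast, background 100) plus Gaussian noise (SD 20). The
  noiseless image realizes the target contrast exactly; contrast targets
  are uniform on 0.01–0.25, matching the squared-contrast magnitudes
  implied by clinical TZ/PZ signal ratios;
- **raters**: each rater displaces the true surface by a band-limited
  Gaussian radial field with RMS amplitude equal to their
  `boundary_noise_mm`, plus a constant bias. Defaults: experts 1.0 mm,
  seniors 1.2 mm, juniors 1.3 mm — chosen so the three groups' consensus
  DSCs are near-equal, as observed in practice. The noise is spatially
  correlated along the contour (8 mm), *not* i.i.d. voxel flips, which
  would destroy Hausdorff semantics. The amplitude is doubled (default
  multiplier 2) on the apical and basal thirds of the structure's extent,
  emulating the poorly contrasted gland extremes. The simulated TZ is
  clipped to the same rater's simulated WG;
- **sub-voxel accuracy**: the surface is displaced on the *analytic*
  radial signed distance of the continuous blob, not on a distance
  transform of the rasterised mask — an EDT to voxel centres quantises
  away sub-voxel displacements and would shrink the effective noise
  several-fold. For truths without an analytic form an EDT fallback
  exists, with exactly this caveat;
- **noise scaling**: noise is absolute (mm), not volume-proportional, so
  the clinical volume-vs-agreement relationship *emerges* (small glands
  have relatively larger boundary uncertainty) instead of being assumed.
  Optionally, `contrast_noise_coupling` scales each case's noise by up to
  `1 + coupling` as its zone contrast approaches the bottom of the
  contrast range, modelling harder contouring on poorly differentiated
  glands — off by default, since it is one of the effects under study;
- **annotations**: lesion (prevalence 0.425, the clinical fraction of
  PI-RADS ≥ 3) and median-lobe flags are sampled independently of the
  noise, i.e. as null factors, matching the finding that neither affects
  agreement;
- **2D acquisitions**: the same case anatomy (volume, TZ fraction,
  contrast are drawn from a grid-independent stream) can be re-rasterised
  on a thick-slice grid to emulate a 2D T2W subgroup;
- **determinism**: the cohort is a pure function of `(spec, seed)`;
  randomness expands through counter-based `SeedSequence` spawn keys per
  (case, rater, structure, grid), so extending a cohort never perturbs
  existing cases.

What passing tests on this generator shows: that the metrics, consensus,
regional split and statistics do what they claim on data with the right
covariance structure (correlated contours, nested zones, volume and
contrast gradients, three noise-level groups). What it does not show:
robustness to real MRI texture, motion or bias-field artefacts, anatomical
pathology (median lobes are a flag, not a deformation model), or
inter-rater *systematic* disagreement about anatomy definitions — real
raters disagree about where the base ends, not just by how much their
hands wobble.

## Statistical layer

The sampling unit is the case: metric records are averaged over the 21
rater pairs (or over a group's raters in the consensus frame) within each
case before any test — pooling pairs would pseudo-replicate, since one
case's pairs share its anatomy. This ordering is asserted by a test where
the two weightings differ.

- paired Wilcoxon signed-rank for related samples, Pratt treatment of zero
  differences; exact null when n ≤ 25 with no zeros or ties, otherwise
  normal approximation with continuity correction. An all-zero difference
  vector is reported as a degenerate comparison with p = 1;
- Mann–Whitney U for independent samples; exact null for tie-free groups
  of ≤ 25, otherwise asymptotic with continuity correction;
- Spearman ρ with a 95% CI from the Fisher z-transform using the
  Spearman-adjusted standard error `sqrt((1 + ρ²/2)/(n − 3))`; ties get
  average ranks. These wrappers are verified against base R
  (`wilcox.test`, `cor.test`) to 1e-8 on fixed fixtures;
- Holm–Bonferroni step-down adjustment, with running-maximum monotonicity
  and capping at 1, applied per analysis block (the three regional
  contrasts; the three group contrasts per metric; the morphology
  correlations per frame). The block-per-table family definition is a
  reconstruction — reader studies rarely enumerate their families — and is
  configurable by passing any set of reports to `holm_family`.

Under a simulated null (equal-noise groups, permuted covariates, random
binary factors) the Holm-adjusted rejection rate at nominal 0.05 stays at
or below 0.07 over 200 replicates.

## Problem sizes

Tests and the acceptance script run cohorts of 10–20 cases on isotropic
1.5 mm grids — coarse enough that a full simulate → consensus → metrics →
stats cycle takes seconds per case, while every effect of interest (volume
and contrast gradients, regional ordering, consensus superiority, group
separation) remains detectable at n = 20. The default `CohortSpec`
mirrors the emulated study itself (40 cases, 0.6 × 0.6 × 1.0 mm); at that
resolution a full run takes tens of minutes and a few GB of memory.

## Known limitations

- No DICOM series reading, registration, or resampling between mismatched
  geometries; masks of one case must share a grid.
- The generator's blobs are star-shaped about their centre; strongly
  non-convex anatomy (pronounced median lobes) is out of its reach.
- Multi-label STAPLE, spatially varying priors, and MAP variants with beta
  priors on (p, q) are not implemented.
- `mask_ellipsoid_dims` is a convenience, not a clinical measurement
  protocol; its volumes inflate by about one voxel per diameter.
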