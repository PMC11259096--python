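# Methods

This note documents the models, conventions and numerical choices behind
`angiokit`, in the order the pipeline runs.

## Coordinate and unit conventions

Arrays are `(z, y, x)` (3D) or `(y, x)` (2D); voxel indices are 0-based;
regions of interest are half-open index intervals; the physical position
of a voxel is its **centre**, so a straight run of n voxels spans n − 1
inter-centre steps. All lengths are micrometres, areas mm², volumes mm³
(1 mm³ = 10⁹ µm³). Network-length density is reported explicitly as
µm · mm⁻³ because the quantity is unit-bearing and easily mis-scaled.

## Vessel phantoms

Phantoms are the validation substrate: tubes rasterized around known
centerlines, so every downstream metric has an exact expected value.

- **Geometry.** Centerlines live in physical coordinates; voxels are
  foreground when their centre lies within the tube radius of a
  centerline, measured in physical units, so anisotropic voxels (the
  typical 5 µm z-step) are handled correctly. Topologies: a straight tube,
  a symmetric Y (35° arms), and random trees grown by recursive
  bifurcation (base angle 32°, Gaussian jitter; segment lengths uniform
  within ±30% of the mean). Centerlines are snapped to voxel centres:
  exact half-grid placement is a degenerate mirror symmetry no real
  acquisition produces, and it needlessly stresses the thinning.
- **Clearance.** Non-adjacent segments must keep a minimum centerline
  separation of 2 r + 3 σ_PSF + one voxel: 2 r keeps tube surfaces apart,
  3 σ_PSF keeps their blurred halos from bridging at binarization, one
  voxel absorbs rasterization rounding. Only the parent and sibling of a
  new branch are exempt, and only within 2× the clearance of the shared
  junction, where the tubes genuinely meet. A growth that stalls short of
  the target segment count is redrawn from the same random stream, so the
  phantom remains a pure function of its seed.
- **Intensity model.** Foreground/background plateaus (defaults 200/20),
  an isotropic-in-physical-units Gaussian PSF (default σ = 1 µm) applied
  before additive Gaussian noise (default sd 10) — the order of a real
  acquisition. Stack geometry defaults mimic thin confocal volumes
  (~25 slices over ~100 µm when run anisotropically; the validation
  phantoms use 1 µm isotropic grids so that skeleton positions are not
  grid-quantized in z).
- **Ground truth.** Per-segment polylines and lengths, junction and
  endpoint counts (satisfying the tree identity endpoints + junctions =
  segments + 1), and the noise-free rasterized mask.

The other generators: mask pairs whose overlap fraction is realized
*exactly* (shared voxel count = round(f·|A|), the realized fraction
reported); spheroids as a disk core plus radial rectangular protrusions,
whose union area is closed-form (πr² + n·w·l, the attachment sliver being
sub-pixel); dot-blot membranes with duplicate spots, positive/negative
reference pairs, blur, noise, and a global gain/offset applied *after*
noise so that, for a fixed seed, the distorted image is an exact affine
map of the undistorted one. Seeding arithmetic: holding endothelial
density D fixed, an endo:stroma ratio a:b implies a stromal density
D·b/a (500,000/mL at 2:1, 1:1, 1:2 gives 250k, 500k, 1M cells/mL).

## Preprocessing

Per-slice 2D blur → background filter → threshold → 3D clean, matching
the convention that optical sections are conditioned individually while
all analysis after binarization is 3D. The original acquisition macro's
parameters are not published, so the defaults are explicit choices,
recorded in the mask's provenance and overridable: Gaussian σ = 2 µm
(converted to pixels via calibration), median filter 3 px (or white
top-hat), Otsu per slice, minimum object 27 voxels (3³).

Threshold methods and when to use them:

- `otsu_per_slice` — when every optical section contains signal.
- `otsu_global` — one threshold from the full-volume histogram; required
  for sparse stacks where some slices are background-only (per-slice Otsu
  on a signal-free slice splits the noise). The phantom-recovery analyses
  use this.
- `intermeans_global` — Ridler–Calvard iterative intermeans.
- `halfmax` — threshold at the midpoint of robust (0.1/99.9 percentile)
  extremes: the full-width-at-half-maximum criterion, which recovers the
  boundary of a blurred two-level object without the class-imbalance bias
  of histogram methods.
- `fixed` — explicit value.

A known limitation, quantified on phantoms: any threshold-based
segmentation of a tube whose radius is only ~3× the PSF misplaces the
boundary by a curvature-dependent offset of order σ²/r, so mask-extent
recovery (IoU against the rasterized truth) is only near-perfect in the
mild-blur regime. Skeleton topology and length are insensitive to this
uniform dilation, which is why the recovery criteria are stated on
topology and length, not IoU.

## Skeletonization and the skeleton graph

The mask is thinned by 3D topological thinning (scikit-image). Thinning
preserves connected components; as a guard, any component the library
erodes to nothing (an orientation-sensitive corner case for exactly
grid-symmetric even-width objects) is re-thinned under a transposed axis
order and merged back.

Graph decomposition: endpoints are skeleton voxels with exactly one
26-neighbour, junction voxels have ≥ 3; touching junction voxels are
merged into a single node (centroid coordinate) because raw thinning
produces junction clumps that would otherwise inflate branch-point
counts. Segments are maximal paths between nodes; their length is the sum
of physical centre-to-centre steps (√(Δx² + Δy² + Δz²) in µm — diagonal
steps and z-anisotropy handled exactly), including the step onto the
junction voxel they attach to. A closed ring with no degree ≠ 2 voxel is
one cyclic segment with no nodes. An isolated voxel is an endpoint node
with no segments.

Two artifact-repair passes, both logged and both off at `prune_um = 0`:

1. **Spur pruning** — terminal segments shorter than `prune_um` hanging
   off a junction are removed at the voxel level and the graph rebuilt
   (iterated to a fixed point). Default 3 µm; analyses of tubes of known
   radius use 2 r, the scale of the medial-axis wedge artifact at a
   bifurcation of radius-r tubes (r/tan(θ/2) ≈ 1.6 r at 2×32°).
2. **Junction-link contraction** — junction pairs connected by a segment
   shorter than `prune_um` are merged into one node: thinning can split a
   single anatomical branch point into two clusters a few voxels apart.

Metric definitions, fixed by the relation *average branch length = total
network length / number of vessels*: `n_vessels` = number of segments;
`n_branches` = branch points + endpoints; both are reported separately so
either counting convention can be recovered. `avg_branch_length_um` is
missing (not zero) for an empty graph. ROI averaging is the unweighted
arithmetic mean of each metric across the ROIs of one gel.

Validation: on seeded random-tree phantoms (radius 3 µm, ≥ 10 segments)
endpoint and junction counts are recovered exactly and total length
within a few percent (the skeleton runs marginally long at junction
crossings and marginally short at tube ends).

## Colocalization

`overlap` counts Σ(A·B) over same-shape binary masks. The headline
"degree of overlap" defaults to n∩/n_A with A the vessel mask, but all
three normalizations (over A, over B, Jaccard) are always computed and
reported, making the denominator ambiguity harmless. Binarization of both
channels goes through the preprocessing module so masks share provenance.

## Spheroid outgrowth

Areas are body-inclusive (the fold change normalizes to the whole initial
spheroid). Manual masks are first-class inputs, matching traced
measurement; `threshold_auto` Otsu-segments the image (dark-object
convention for brightfield), keeps the largest connected region and fills
holes. Replicate traces (1–3) are arithmetically averaged. Fold change is
(A_d − A_0)/A_0, dimensionless and invariant to uniform rescaling of both
areas. Per-group day-3 fold changes feed the statistics module unchanged.

## Densitometry

Spot densities are disk means (the measurement radius defaults to the
printed spot radius minus 2 px to stay inside the blurred rim); duplicates
are averaged; normalization is (d − mean(neg)) / (mean(pos) − mean(neg)).
This maps negative references to 0 and positive references to 1 and is
*exactly* invariant to global affine intensity distortion — the reason
this form was chosen over dividing by the raw positive mean. A strict
`pos_denominator` mode provides the alternative (d − neg)/pos for pipelines that
normalized that way. A membrane whose positive controls do not exceed the
negatives is rejected rather than silently normalized.

The interaction-graph summary consumes a user-supplied edge list (no live
database dependency): simple undirected graph, duplicate edges collapsed,
self-loops rejected; average degree 2E/N; mean local clustering with
degree < 2 nodes contributing 0.

## Routed statistics

Gate: Shapiro–Wilk **per group** (the conservative reading for n = 3–6;
pooled-residual testing is a configuration away), with "normal" meaning
every group's p > α. Variance: Bartlett when normal — Bartlett assumes
normality — otherwise the median-centred (Brown–Forsythe) Levene. Routing:

| normal | homoscedastic | omnibus | post-hoc |
|---|---|---|---|
| yes | yes | one-way ANOVA | Tukey HSD |
| yes | no | Welch ANOVA | Games–Howell |
| no | yes | Kruskal–Wallis | Dunn |
| no | no | trimmed-means Welch F | Games–Howell |

Implementation notes:

- **Welch ANOVA** uses weights n_i/s_i²; with two groups it reduces
  exactly to the squared Welch t statistic.
- **Trimmed Welch F** replaces means by γ-trimmed means (default
  γ = 0.2, the standard choice) and squared standard errors by
  (n−1)s²_w/(h(h−1)) with h the post-trim count and s²_w the Winsorized
  variance; γ = 0 reproduces Welch exactly.
- **Games–Howell**: pairwise Welch t with Welch–Satterthwaite df,
  referred to the studentized-range distribution at q = |t|√2 with the
  full group count k; p-values are family-wise by construction. In the
  equal-variance, equal-n limit it converges to Tukey HSD.
- **Dunn**: pooled-rank z statistics with the tie correction
  Σ(t³−t)/(12(N−1)) removed from the rank variance; adjustment defaults
  to Holm (Bonferroni and none available).
- **Kruskal–Wallis**: tie-corrected H; when the number of distinct group
  assignments is ≤ 20,000 (e.g. 1680 for n = (3,3,3)) the p-value is
  computed by exhaustive enumeration of the permutation distribution of
  H instead of the chi-square approximation, which is unreliable at the
  sample sizes this battery is built for.
- With n = 3 per group the normality gate has negligible power; the
  router attaches a low-power warning (groups under 8) rather than
  refusing to test.

Calibration: over 2000 null simulations (3 groups, n = 6, standard
normal) the routed omnibus rejects at 4–6% at α = 0.05 — the gate's
pre-testing does not distort the level materially.

## Pipeline and determinism

One YAML config drives phantom generation (or an input manifest),
preprocessing, skeleton metrics, ROI averaging and the routed comparison.
All randomness flows from a single root seed through named substreams
(one per condition, spawned in sorted condition order), so stages re-run
independently yet reproducibly and a rerun is byte-identical. The
provenance log records every parameter, including defaults that were
applied implicitly, and the package version.

## Problem sizes used in validation

Phantom-recovery checks use 25×30×220 to 64×200×200 voxel grids at 1 µm,
ten tree seeds, radius 3 µm; the demo pipeline uses 16×100×100 grids at
2 µm with three gels × three ROIs per condition; statistical calibration
uses 2000 simulations. These sizes were chosen so the full validation
battery runs in well under a minute while every estimator operates far
from its small-sample edge cases.

## What the phantoms do and do not establish

Phantoms have homogeneous plateau intensities, Gaussian PSF and noise,
and clean tubular geometry. Real stacks add depth-dependent attenuation,
autofluorescence, stain heterogeneity, touching non-tubular structures
and cell bodies; passing the phantom battery therefore establishes the
*correctness of the computations* (geometry, units, counts, statistics),
not segmentation robustness on arbitrary real data. Parameters most worth
revisiting on real data: the preprocessing threshold method (global vs
per-slice), the minimum object size, and the spur-prune length relative
to true vessel radius.
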