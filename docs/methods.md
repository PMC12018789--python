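# Methods

`pollenflow` reimplements, as an open and tested pipeline, a
high-throughput workflow for measuring pollen grain size from imaging
flow cytometry (IFC) brightfield images: segmentation masks, six size
features, quality gating, bead-based calibration, hierarchical size
summaries, method-agreement statistics and a phylogenetic-signal test.
This note documents the models, the numerical choices, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Imaging model and synthetic galleries

An imaging flow cytometer delivers one particle per frame in a
transmitted-light (brightfield) channel: the object appears dark on a
bright background by absorption contrast. The generator renders an ideal
binary silhouette (antialiased with 4x4 subpixel coverage), sets object
intensity to `background - contrast` (defaults 0.8 and 0.5 on a [0, 1]
scale), blurs with an isotropic Gaussian standing in for the optical PSF
(default sigma 0.5 um = 1 px at the x40 pixel size), and adds Gaussian
noise clipped to the valid range (default SD 0.01, i.e. 2% of the object
contrast). Pixel sizes follow the instrument: 0.5 um at x40, 1.0 um at
x20. The frame side is 1.8x the object's longest dimension (minimum
16 px), so only the `cropped` class touches the border; the particle
count per gallery is capped at 5000, mirroring the acquisition stop.

Shape classes and their geometry (all sizes are the true longest
dimension, which the ground-truth table records exactly):

- **bead** — perfect disk; the calibration standard (certified latex
  beads, modal diameter 19.98 um).
- **spheroid** — disk with a low-order Fourier radial roughness
  (relative SD 0.02, harmonics 2-6) standing in for pollen sculpture;
  radially parameterised shapes are rescaled after the perturbation so
  the longest extent equals the nominal size exactly.
- **oblate, polar / equatorial view** — an oblate grain seen pole-on
  (near-circular outline) or side-on (ellipse of the grain's aspect
  ratio, default 1.6). The longest visible dimension equals the grain
  size in both views; the views differ in elongatedness, which is what
  view sorting exploits.
- **elongated** — capsule of aspect 3 (rectangle with semicircular caps).
- **saccate** — corpus disk of diameter `d` plus two air sacs of diameter
  `0.6 d` centred at `+-0.55 d`, a one-parameter Pinaceae-like
  silhouette; the union spans `1.7 d`.
- **debris** — small (default 6 um), low-contrast (0.25), strongly
  irregular blob.
- **doublet** — two touching disks of radius `R` with centres `1.8 R`
  apart (union spans `3.8 R`), giving the deep neck typical of grain
  pairs.
- **cropped** — a grain placed so the frame border clips it.

Galleries are written as 16-bit TIFF (or 8-bit PNG) plus a `truth.csv`
with per-object class, true length and area, view, and sample labels.
A `SpeciesDesign` assigns pollen objects to individuals and years with
seeded Gaussian effects (defaults: between-individual SD 1.0 um,
between-year SD 0.5 um, within-sample SD 2.0 um around a 32 um species
mean), so hierarchical summaries can be scored against configured
effect sizes.

What the generator does **not** emulate: intensity texture (pori,
sculpture beyond the silhouette roughness), diffraction, shot noise,
fluorescence, 3-D orientation distributions, or overlapping multi-grain
clumps beyond simple doublets. Passing tests therefore demonstrate that
the measurement and gating machinery is correct on silhouettes with
known truth — not that the gates are optimal for any particular real
taxon.

## Masks

- **Object mask**: Gaussian-smooth (sigma 1 px) the contrast map
  `|I - background|`, threshold by Otsu's criterion, keep the largest
  8-connected component, fill holes. The background is the median of the
  3-px border frame (single-object frames have object-dominated
  interiors); the robust contrast scale is the 99th percentile of
  `|I - background|`. Images with no pixel above a configurable contrast
  floor (default 0.1) raise an "empty object" error and are carried
  through the pipeline with an error status rather than dropped.
- **Adaptive-erode mask AE(OM, t)**: normalised contrast
  `c = |I - background| / scale` clipped to [0, 1] is thresholded at
  `tau(t) = (100 - t) / 10` (clipped to [0, 1]) inside the filled 1-px
  dilation of the object mask; the component containing the object
  centroid is kept and holes filled. The mapping makes `t = 100` keep
  every nonzero-contrast pixel, is monotone (masks are nested in `t`),
  and places the default `t = 95` cut at **half-maximum contrast** — for
  a symmetric PSF the unbiased estimate of the true edge position, which
  is why the bead-recovery contract below holds. The vendor's
  AdaptiveErode algorithm is proprietary; this construction is validated
  the same way the original workflow was — by recovery of the certified
  bead diameter — rather than by algorithm identity. Meaningful
  thresholds lie in (90, 100]; below that the cut saturates at the
  contrast plateau.
- **Loose default mask**: filled dilation of the object mask by 4 px,
  emulating the looseness of vendor default masks. Only the
  *ordering* (loose > adaptive-erode modal size) is asserted; the
  absolute overestimation offsets reported for specific instruments are
  vendor-specific and not reproduced.

## Size features

All features are measured on the adaptive-erode mask, in micrometres;
intensities (summed background-subtracted absorption) on the object
mask. Failed objects get NaN features and a status code so gating
accounting conserves counts.

- `area_um2` — pixel count x pixel area.
- `diameter_um` — equivalent circular diameter `2 sqrt(area / pi)`,
  exact by construction (this is a derived, not measured, distance).
- `height_um`, `width_um` — longer and shorter side of the minimum-area
  *rotated* bounding rectangle (rotating calipers over the convex hull
  of pixel centres, +1 px per side for the pixel footprint). A rotated
  rectangle keeps the features orientation-free.
- `major_axis_um` — `4 sqrt(lambda_max)` of the pixel-coordinate
  covariance (with the 1/12 pixel-square term), i.e. the major axis of
  the moment-equivalent ellipse.
- `length_um` — geodesic diameter: the longest shortest path between
  boundary pixels that stays inside the mask, +1 px endpoint
  correction. Computed on a Euclidean-weighted **visibility graph** over
  boundary pixels: two nodes are joined when the straight segment
  between their centres stays inside the mask (sampled every 0.7 px),
  and shortest paths are taken with Dijkstra. In a polygon, geodesics
  bend only at boundary reflex points, so boundary nodes suffice. On
  convex masks every pair is visible and the result is exactly the
  maximum Feret diameter of the pixel centres; on folded masks the path
  follows the fold. Chamfer-graph alternatives (unit/diagonal step
  costs) were rejected because their directional bias (up to +8.2% on
  straight lines) is always picked up by the max-over-pairs diameter,
  which would break both the convex-Feret equivalence and the bead
  calibration. Boundaries longer than 512 px are decimated evenly along
  the traced contour; the residual error is bounded by the node spacing
  (<= 2% on the shapes in the test suite).
- `thickness_max_um` — largest inscribed-disk diameter,
  `2 x max` of the Euclidean distance transform. The transform measures
  to the nearest *background pixel centre* (half a pixel beyond the
  physical boundary), which exactly offsets the half pixel the deepest
  foreground centre sits inside, so no further correction is applied (a
  20 x 10 px rectangle yields exactly 10 px).
- `circularity` — mean over boundary pixels of the distance to the
  centroid divided by the SD of that distance (`mu_R / sigma_R`), capped
  at 100. Scale-invariant; high for circles (sigma_R -> 0), ~6 for a
  1.6:1 ellipse, ~3 for touching doublets. Only its ordering is used.
- `elongatedness` — bounding-rectangle aspect ratio (>= 1).

Discretisation bias: rasterising a disk of true diameter `D` px and
adding the +1 px footprint correction yields extents of about
`D + 0.9` px (the union of pixel squares genuinely overhangs the
analytic outline). At the bead diameter (40 px) this is ~0.45 um,
within the one-pixel calibration contract; relative bias shrinks as
`1/D`.

## Gating cascade

Stages run in order; every object receives exactly one terminal label
(`debris`, `multiple`, `cropped`, `outlier`, `hq_single`), so labels
partition the input. All automatic thresholds can be overridden from
the run configuration and are recorded for replay.

1. **Debris** — per-channel Otsu threshold on `log10(1 + intensity)` of
   the two brightfield cameras (debris is below threshold on both; with
   one camera, on the single histogram). Otsu's criterion is flat across
   an empty inter-cluster gap, so the raw threshold can land at a
   cluster edge; the automatic threshold is therefore snapped to the
   midpoint of the widest inter-point gap near it, and it is only
   applied when that gap spans at least 0.3 log10 units (a factor 2 in
   intensity): debris carries at least an order of magnitude less summed
   absorption than pollen (intensity scales with area x contrast),
   whereas a threshold that bisects a continuous debris-free population
   sits inside the data, where gaps between adjacent order statistics
   are ~sigma/n. Without this guard Otsu would split any clean sample
   in half.
2. **Singlets** — multiplets form the lowest circularity mode. The gate
   cuts at the KDE valley separating the lowest mode from the next one,
   and only when that lowest mode lies below a physical ceiling
   (default 4.5): the radial-spread ratio of a touching pair of convex
   grains is scale-invariantly below ~4.5, while single convex profiles
   up to ~2:1 aspect lie above it. This keeps equatorial-view oblate
   singles (circularity ~6) from being cut when the density's deepest
   valley happens to separate shape subpopulations rather than
   multiplets.
3. **Cropped** — border-touch flag of the object mask.
4. **View sorting** — for species configured as nonspherical, the
   elongatedness histogram is split at its deepest KDE valley between
   the outermost modes: above = equatorial (elongated profile, longest
   dimension visible), below = polar. Unimodal densities label
   everything polar with a warning.
5. **Outliers** — modified z-score (0.6745 (x - median)/MAD) above 3.5
   on log area or on elongatedness, evaluated **within species x view
   strata**. View sorting runs before this stage because the MAD rule
   presumes a homogeneous population: on a polar/equatorial mixture the
   median and MAD sit inside the polar cluster and every equatorial
   grain would be flagged. Strata with fewer than 8 records skip the
   stage with a warning.

KDE details: Gaussian KDE with half the Scott bandwidth (Scott's rule
targets unimodal densities and oversmooths well-separated gate
clusters); modes closer than 0.15 (log10 circularity units /
elongatedness units) are merged, since tight quantised clusters
otherwise produce spurious micro-modes. Circularity is analysed on a
log10 scale.

Heterospecific-pollen removal is out of scope (no classifier); the
outlier gate is the only defence against contamination.

## Summaries and calibration

Species size summaries are reported at two levels: pooled over all
pollen, and over per-individual means (equal weight per individual
plant), the latter de-biasing species means under uneven per-individual
sampling. The modal size uses a histogram with bin width equal to one
pixel, bins anchored at zero, ties resolved to the lowest bin.

The calibration contract ties everything together: over 1000 synthetic
beads at the certified modal diameter (19.98 um, 0.5 um/px, 1 px blur,
2% noise), the modal `Length` through AE(OM, 95) must equal the true
diameter within one pixel, and the loose default mask's modal size must
strictly exceed it.

## Method agreement

Bland-Altman analysis with the sign convention `IFC - literature`
(negative mean difference = literature larger), limit lines at the mean
difference and +-1 and +-2 SD of the differences. When literature
sources give min/mean/max, the mean is the comparator. Pearson
correlation (two-sided t-based p) and simple OLS — optionally on
log10-transformed literature sizes — with adjusted
`R^2 = 1 - (1 - r^2)(n - 1)/(n - 2)` and `df = n - 2` rank agreement
across sources; correlation alone is never treated as agreement.

## Phylogenetic signal

Blomberg's K compares the observed ratio of the non-phylogenetic MSE
(about the phylogenetically weighted mean
`a = (1' V^-1 1)^-1 1' V^-1 x`) to the phylogenetic MSE
`(x - a)' V^-1 (x - a)/(n - 1)` against the Brownian-motion expectation
`(tr V - n/(1' V^-1 1))/(n - 1)`, where `V` is the shared
branch-length matrix. K = 1 matches Brownian motion on the tree
(exactly so on star phylogenies, which the tests verify to 1e-10, and
the implementation agrees with `phytools::phylosig` to 1e-8 on random
trees). A root stem edge, e.g. left by pruning, is counted as shared by
all tips so that pruning commutes with V.

Significance is a one-sided randomization test (trait values shuffled
across tips) with `p = (1 + #{K_perm >= K_obs})/(n_perm + 1)`, which
can never return 0 and matches the resolution of the workflow's
reported p-values at n_perm = 1000. Tests use n_perm = 200 to keep the
type-I simulation (400 null runs) inside a few minutes; the estimator
is the same.

Tree utilities: Newick round-trips (underscore labels preserved),
pruning (collapsing unary nodes, summing branch lengths, purging unused
taxa), rename maps for taxonomic updates, and genus-level tip addition
for species absent from a reference phylogeny: with >= 2 congeners the
new tip attaches at their MRCA with a pendant branch equal to the mean
clade depth; with a single congener at the midpoint of its terminal
branch. Both rules preserve ultrametricity; the single-congener
attachment depth is a documented convention (reference implementations
vary here), so external K reproductions may differ in the second
decimal.

## Problem sizes and determinism

Default simulation sizes were chosen to give stable statistics at
desk scale: 1000 beads for calibration, a 600-object mixed gallery
(45% spheroid, 12.5% + 12.5% oblate views, 10% each debris / doublets /
cropped) for gating recovery, 500 Brownian replicates on a 50-tip
coalescent tree for the K calibration and 400 null runs for the type-I
check. Every stochastic step takes an explicit seed; identical seeds
produce bit-identical galleries, feature tables and p-values. The
`scripts/acceptance.py` entry point recomputes the bead calibration
from scratch with a caller-supplied seed.

## Known limitations

- The adaptive-erode construction matches the vendor mask in intent and
  calibration, not bit-for-bit; vendor Circularity/Elongatedness
  formulas are likewise undisclosed, so only orderings are relied on.
- Geodesic length on boundaries above 512 px uses decimated nodes
  (documented <= 2% error); sub-pixel boundary interpolation is out of
  scope.
- Gates assume one species per sample (as acquired in practice);
  multi-species samples would need a classifier upstream.
- The generator's realism is limited to silhouettes; texture-dependent
  behaviour (e.g. intensity-based gates on real sculpture) is untested
  against real data.
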