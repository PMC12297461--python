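# Methods

nuQLOUD quantifies multicellular tissue organisation from nothing but the
3D positions of nuclear centroids.  This note documents the models and
procedures the package implements, the parameters that matter, the design
choices made where the design was genuinely open, and what the synthetic
data used by the test suite does and does not show about real specimens.

## Adaptively restricted Voronoi tessellation

A conventional Voronoi diagram assigns unbounded cells to nuclei on the
convex hull of a specimen, which makes boundary tissues (skin, enveloping
layers) unusable.  The package therefore initialises every cell as a
**regular dodecahedron** of edge length `edge_length` (default 100 µm,
canonical orientation, centred on its seed) and crops it by the
perpendicular-bisector half-spaces of the surrounding seeds.  Interior
cells are identical to ordinary Voronoi cells; cells that retain at least
one face of their initial dodecahedron are flagged *boundary*.

Implementation: a global `scipy.spatial.Voronoi` pass handles every cell
that is bounded and strictly inside its dodecahedron; the remaining cells
are clipped per seed with Qhull half-space intersection, discovering
bisector candidates iteratively inside the security radius (twice the
current maximum vertex distance).  Volumes and centroids come from a
tetrahedral decomposition of the cell hull.  Faces with area below
1 × 10⁻⁹ µm² are ignored for adjacency, and adjacency is kept symmetric by
requiring both cells to detect the shared face.

**Degeneracy.** Perfect lattices are cospherical and break incremental
convex-hull codes.  All seeds are jiggled deterministically (fixed internal
seed) by 10⁻⁹ × the median nearest-neighbour spacing before tessellation.
The jiggle converts degenerate contacts into slivers of width ~the jiggle
amplitude; the face filter therefore also rejects faces whose area is
below 10 × (jiggle amplitude) × (face diameter).  Analytic assertions in
the tests carry 10⁻⁶ tolerances accordingly.

**Boundary closure.** A second, adaptive pass closes boundary cells at the
scale of their local neighbourhood: every boundary cell's face neighbours
are mirrored through its seed (`2·x_i − x_j`), the reflections are
deduplicated (10⁻⁶ µm) and dropped if they collide with a real nucleus
(10⁻³ µm), and the union of real and auxiliary seeds is re-tessellated.
Cells are only reported for real nuclei.  Two refinements proved necessary
in practice:

* **Extended cells.**  On small, strongly curved specimens, cells just
  beneath the hull can be *caged* by distant bisectors without retaining a
  dodecahedron face, while still reaching far outside the cloud (vertex
  radii of 20–120 µm at 3–5 µm spacings).  Such cells are flagged
  *extended* when some cell vertex lies further than 1.5 × the local
  median neighbour distance from **every** seed — i.e. the cell has
  geometry in space that no nucleus covers.  Extended cells emit
  reflections and are allowed to be capped.  On large specimens the flag
  coincides with the face-based boundary flag.
* **Interior protection.**  A reflection is dropped if it would cut any
  *local* interior cell (a new seed cuts cell k iff some vertex of k is
  closer to the new seed than to k's own seed).  This makes the guarantee
  exact: locally determined interior cells are bit-for-bit invariant
  (≤ 10⁻⁹ relative volume) under the closure pass, while boundary wedges
  shrink monotonically.  On the embryo fixture this caps the largest cell
  from ~3.5 × 10⁵ µm³ to ~2.4 × 10⁴ µm³.

A note on scale: with 100 µm bounding solids, effective closure requires
the specimen's surface curvature radius to be large against the solid; at
the few-hundred-µm fixture scale a residual crust of partially capped
cells remains.  This is a property of the scaled-down test geometry, not
of the method.

## The 14 organisational features

Per nucleus (units in brackets):

| class | feature | definition |
|---|---|---|
| density | `density_0_10`, `density_10_20`, `density_20_30` [µm⁻³] | counts of other nuclei in the concentric shells (0,10], (10,20], (20,30] µm divided by shell volume |
| density | `voronoi_density` [µm⁻¹] | mean inverse distance to face-sharing (Delaunay) neighbours |
| anisotropy | `voronoi_volume` [µm³] | restricted Voronoi cell volume |
| anisotropy | `centroid_offset` [µm] | ‖cell centroid − seed‖ |
| anisotropy | `polarity` [–] | centroid offset / volume^{1/3} |
| irregularity | `n_neighbours` [count] | face-sharing neighbours (real nuclei only) |
| mixed | `nbh_mean_*`, `nbh_std_*` | mean and *population* standard deviation of volume, neighbour count and centroid offset over the immediate Voronoi neighbourhood, self excluded |

The shell densities are deliberately plain counts over shell volumes (no
smooth kernel): a self count would add a constant, information-free
1/V offset, so the focal nucleus is excluded.  Population-form standard
deviations keep single-neighbour cells finite (std 0).  `polarity` is the
dimensionless companion of the centroid offset; it can be disabled in the
feature configuration, which drops the table to 13 columns.

**z-scoring** pools means and standard deviations across *all* samples of
a dataset, preserving inter-sample differences; the parameters are stored
on the table so partial datasets can be placed on the same scale.
Constant features raise rather than silently producing NaNs.

**Feature classes.**  Per-sample feature×feature Pearson correlations are
averaged across samples, converted to the distance 1 − r, and Ward-linkage
clustered; cutting at three classes recovers the density / anisotropy /
irregularity grouping, with labels assigned by maximal overlap against the
canonical membership above (Hungarian assignment).

## Motifs and archetypes

**Motifs** are components of a full-covariance Gaussian mixture over the
z-scored features (default K = 11).  The fit is deterministic given a
seed: k-means (10 restarts) provides the initial means and weights, EM
runs to a tolerance of 10⁻⁴ on mean log-likelihood or 500 iterations, and
covariances carry a 10⁻⁶ diagonal floor.

**Component-count diagnostics** (`select_motif_count`) report, per K: mean
silhouette on a ≤ 10⁴-cell subsample, BIC, and a Monte-Carlo estimate
(10⁴ draws per model, seeded) of the Jensen–Shannon divergence between the
K- and (K−1)-component mixtures.  The JSD "gradient" is its finite
difference over K, and the recommended K is the first interior local
minimum of that gradient, ties toward smaller K.  Comparing successive
mixtures is one reading of a dissimilarity-gradient criterion; it is a
declared choice, as is the Monte-Carlo estimator (there is no closed form
for the JSD of Gaussian mixtures).

**Archetypes** agglomerate motif mean profiles with Ward linkage and cut
the tree at two groups.  Two robustness choices matter at test scale:

* near-empty components (weight < 0.005) are excluded from the dendrogram
  — they typically contain a handful of extreme boundary cells whose
  outlying profiles would otherwise dominate the top split — and are
  attached to the nearest archetype centroid afterwards;
* the Ward objective is weighted by motif cell mass (implemented exactly
  by row replication at 1/1000 resolution), so the costliest merge
  separates cell populations rather than isolating a small outlying
  motif.

Euclidean distance between profiles is the default; a correlation
distance (1 − Pearson of profiles) is available.  On the synthetic fixture
the two are *not* interchangeable: under correlation distance the
near-surface motifs (whose shells are truncated by the specimen boundary,
tilting their profile toward "low density") join the crystalline side.
With two archetypes the group whose profile has the higher mean over the
density-class features is named **amorphous** (dense, isotropic,
irregular), the other **crystalline** (low-density, anisotropic, regular);
this replaces anatomical inspection with an unambiguous rule.

`feature_importance` trains a random forest (200 trees, seeded) on the
motif labels; importances below 1/(10 · n_features) are flagged
underutilised.  `archetype_robustness` refits motifs at K ∈ {2, 4, 8, …},
cuts archetypes at two, and reports pairwise adjusted Rand indices of the
per-cell labels.

## Expression calling

Nuclear-localised signals are averaged in a sphere of radius
2 × nuclear radius around each centroid (the dilation factor and radius
are configurable; centroids outside the volume yield NaN, never 0).
Cytosolic/punctate signals are integrated over the Voronoi cell: a voxel
belongs to the cell whose seed is nearest *and* whose bounding dodecahedron
contains it, so every voxel is counted at most once and total intensity is
conserved exactly.

The pooled intensity distribution is decomposed into two 1D Gaussians by
EM (seeded k-means initialisation); the lower-mean component is noise and
a nucleus is *expressing* when its posterior probability of the signal
component exceeds 0.5 — the minimal-assumption decision rule for a stated
noise/signal decomposition.  Fits whose means are closer than 0.1 pooled
standard deviations are flagged degenerate and yield all-non-expressing
calls.  Otsu splitting (256-bin histogram) and min–max line-profile
normalisation (optional scalar background subtraction) complete the
thresholding utilities.

## Pair correlation g(r)

g(r) is estimated in contiguous shells of width `dr` (default 2 µm) up to
`r_max` (default 50 µm, spanning the feature length scales): observed pair
density over the density expected for a homogeneous Poisson process of the
counted set's intensity (count / convex-hull volume).  Edge effects are
handled by minus-sampling — only reference points deeper than the shell's
outer radius from the hull boundary count — which keeps the estimator
unbiased without a container model; an uncorrected mode exists for
comparison.  Auto mode counts pairs within one set (self pairs excluded);
cross mode counts points of set B around references from A.

## Reference embedding and projection

The 2D reference embedding is a t-SNE with a staged protocol: a random
pre-sample (default 25,000 cells) is embedded from a PCA initialisation
with multi-scale affinities averaged over perplexities 50 and 500, cosine
distance, learning rate n/12, 250 iterations at exaggeration 12 /
momentum 0.5 then 750 at exaggeration 1 / momentum 0.8; remaining cells
start at their feature-space nearest neighbour's coordinates, and the full
embedding is optimised at perplexity 30 for 500 iterations at
exaggeration 4 / momentum 0.5 plus 500 at exaggeration 3 / momentum 0.8.
(The protocol's printed momentum "8" is outside the valid range and is
interpreted as 0.8; the schedule metadata records this.)

Partial data is projected by normalising with the **reference's stored
z-score parameters** (tables z-scored with their own statistics are
rejected), initialising at the nearest reference neighbour, and running
500 iterations at exaggeration 3 / momentum 0.8 with the reference frozen
— freezing keeps projections comparable across queries.  Per-point step
norms are clipped at 0.25 during projection; without the clip the
gain-scaled steps oscillate in the fixed reference potential.

The optimiser computes exact pairwise gradients in float32, so it is meant
for reference atlases of up to a few tens of thousands of cells, not
millions; the workflows here subsample to ≤ 2,500 reference cells.

## Synthetic study conditions

The generators provide ground-truthed stand-ins for the two archetype
phenotypes:

* `make_amorphous` — hard-core random sequential adsorption at intensity
  λ with exact minimum separation h (feasible while λ·π/6·h³ < 0.3; RSA
  jams near 0.38).  h = 0 gives a homogeneous Poisson process.
* `make_lattice` — axis-scaled rectangular lattice with Gaussian jitter
  (< spacing/4).
* `make_embryo` — an ellipsoidal "embryo" (semi-axes 150 × 100 × 100 µm)
  with an amorphous compartment (λ = 6 × 10⁻³ µm⁻³, h = 2 µm) filling one
  half and a crystalline compartment (spacing 9 µm, axis scales
  (1, 1, 1.6), jitter 0.9 µm) filling the other, separated by a 6 µm gap
  (≈ one cell diameter, a sharp tissue boundary).  ~21,500 nuclei, each
  carrying a population label and an interior flag (≥ 30 µm from the
  surface, i.e. beyond the largest density shell).
* `make_intensity_mixture` / `make_blob_image` — labelled two-Gaussian
  intensity draws and Gaussian-blob volumes for the expression stage.

What the fixture does *not* emulate: realistic organ geometries, nuclear
shape and segmentation error, developmental stage structure, and — most
importantly — the surface-to-volume ratio of a real embryo.  At fixture
scale roughly half the cells sit within 30 µm of the surface, so
boundary-truncation effects on the density features are far stronger than
in toto.  Passing tests therefore demonstrate that the pipeline recovers
planted organisational structure and honours its numerical contracts, not
that archetype calls on real specimens are correct.

## Problem sizes and known limitations

The test suite and the acceptance script run the embryo fixture at
~21,500 cells, Poisson calibrations at 10⁵ points, g(r) at 10⁴ points,
mixtures at 10⁴ draws, and embeddings at 2,500 reference cells — sizes
chosen so every study condition recomputes from scratch in minutes on one
CPU.

Known limitations:

* the robustness scan across initial motif counts includes K = 2, where
  the two-component mixture cannot resolve the boundary crust separately;
  at fixture scale the crust (~14 % of cells) sides with the crystalline
  component at K = 2 but is resolved separately at K ≥ 4, so bipartitions
  agree strongly among K ∈ {4, 8, 16} (ARI ≥ 0.97) but only moderately
  with K = 2 (ARI ≈ 0.55).  This is the scaled-down analogue of a
  large-specimen regime in which the crust is negligible;
* archetype naming assumes the density contrast of the two phenotypes;
  on data without a density axis the amorphous/crystalline names are not
  meaningful (the bipartition itself still is);
* exact-gradient t-SNE limits embedding sizes (see above);
* the auxiliary-point rule closes boundary cells laterally on flat
  monolayers but cannot invent out-of-plane neighbours: monolayer cell
  volumes remain bounded by the bounding-solid slab thickness rather than
  by a biological layer thickness.
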