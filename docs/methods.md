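# Methods

`gliamorph` reimplements a joint analysis of microglial morphology and
subcellular transcript localization as measured by MERFISH-style imaging
spatial transcriptomics paired with immunostaining (IBA1 for microglia,
DAPI for nuclei, GFAP for astrocytes). This note documents the models,
the parameters that matter, the synthetic-data generator that stands in
for real acquisitions, and the numerical choices made where the design
was open.

## Coordinate model

All on-disk coordinates are pixels with the origin at the top-left, x
rightward and y downward; z is an integer imaging-plane index. Physical
distances are computed in exactly one place, as
`sqrt((dx * pixel_size)^2 + (dy * pixel_size)^2 + (dz * z_spacing)^2)`,
with `pixel_size` defaulting to 0.108 um/px (typical of commercial
MERFISH instruments at high magnification) and `z_spacing` to 1.5 um.
Because planes are 1.5 um apart while the co-localization radius is
about 1 um, close pairs are in practice same-plane pairs; this mirrors
the acquisition geometry rather than being a simplification.

## Segmentation and compartment decomposition

Coarse IBA1 segmentation of the maximum projection: histogram
equalization, 8-bit conversion, rolling-ball background subtraction,
suppression of pixels whose Sobel edge magnitude falls below the Otsu
threshold of the edge image (removing smooth autofluorescent
background), Gaussian blur, Otsu threshold, connected-component
labeling. Image labels are matched to transcriptomically derived
boundary polygons only when the mapping is unique in both directions;
ambiguous overlaps are dropped, which trades recall for precision.

Per matched cell, adaptive local-mean thresholds (200 px window for the
coarse pass, 50 px for the per-plane pass; offset 2 intensity units,
floored at half the global Otsu threshold so empty background never
passes) produce DAPI and IBA1 masks. The soma is the single connected
DAPI-and-IBA1 component containing the matched coordinate — not all
DAPI overlap — to avoid capturing neighboring nuclei. The process mask
is the cell's IBA1 component minus the soma; per plane, GFAP-positive
pixels are removed from the process mask (astrocyte subtraction applies
to processes only), and the total mask is defined *after* subtraction
as soma plus subtracted process, so per-gene compartment counts satisfy
soma + process = total exactly. Molecules removed by subtraction are
"unassigned", not reassigned.

## Morphometry

The canonical feature vector has exactly 26 named scalars (areas,
perimeters, convexity/solidity/circularity ratios, soma measurements,
Feret diameter, skeleton topology, fractal dimension, lacunarity,
tortuosity). Sholl scalars, per-branch Euclidean/path distances and
intensity summaries are computed but reported as supplementary columns,
keeping the canonical vector stable.

Numerical choices worth knowing:

- **Perimeter.** The mean of the weighted pixel-boundary estimator and
  the Crofton estimator. The two are biased in opposite directions on
  smooth shapes; the average keeps rasterized-disk circularity inside
  (0.95, 1.0] across radii 10–80 px, where either estimator alone
  lands outside.
- **Skeleton topology.** Masks are thinned with a topological skeleton;
  terminal points are skeleton pixels with one 8-neighbor, branch
  points have three or more, and adjacent node pixels are merged into a
  single junction before branches (maximal inter-node paths) are
  traced. Tortuosity averages path length over endpoint chord per
  branch; closed loops count as one branch and are excluded from the
  tortuosity mean.
- **Fractal dimension.** Box counting at dyadic sizes 2 … side/4 on the
  bounding-box crop, with N(s) averaged over the four corner anchorings
  of the grid. Corner averaging makes the estimate exactly invariant to
  translation, 90-degree rotation and flips (a single-corner anchor is
  not, because ragged box edges move under rotation); the fitted slope
  is clamped to the valid planar range [0, 2]. Analytic checks: filled
  square 2.0, straight line 1.0, depth-7 Sierpinski triangle
  log3/log2 ≈ 1.585.
- **Lacunarity.** Gliding-box statistic var/mean^2 + 1 at box size
  ceil(side/8), computed from an exact integer summed-area table so a
  homogeneous fill gives exactly 1.0.
- **Sholl.** Intersections at radius r are connected components of the
  skeleton within the annulus [r − step/2, r + step/2) (step 2 px).
  The annuli tile the plane, so 8-connected diagonal skeleton runs
  (pixel spacing sqrt 2) cannot fall between rings, which a width-1
  annulus allows. The ramification index is the radius-ratio form:
  critical radius over first non-zero radius.

## Morphology embedding and ramification classes

Each cell crop is rescaled so its longer side is 112 px and padded with
middle gray to 224 × 224. The embedding backend is a deterministic
handcrafted multiscale descriptor: a four-level image pyramid with an
8-orientation gradient-magnitude histogram pooled on a 4 × 4 grid per
level (4 × 16 × 8 = 512 values, L2-normalized per level). It satisfies
the same 512-length contract as a pretrained-CNN backend and requires
no network access or weight files.

Embeddings are projected onto their top 10 principal components and
clustered with k-means (10 restarts, seed-derived state) for
k = 1 … 10; k is chosen at the knee of the inertia curve via the
Kneedle criterion (normalized difference-curve maximum, implemented
in-package). Clusters are relabeled C1 … Ck by ascending mean
terminal-point count (ties broken by mean cell area), so C1 is always
the least and Ck the most ramified class.

## Expression statistics

QC removes cells with fewer than 20 molecules or fewer than 5 expressed
genes (inclusive thresholds). Normalization divides by the cell total,
scales to 10,000 and applies ln(1 + x) — natural log for normalization,
log2 only for fold changes. Differential expression is the two-sided
tie-corrected Mann-Whitney-Wilcoxon test per gene with
Benjamini-Hochberg correction across genes; fold changes compare group
means of expm1(normalized) with a 1e-9 pseudocount, and the DEG rule is
strict: log2FC > 1 and adjusted p < 0.05. Compartment enrichment
log-normalizes soma and process count layers independently, restricts
to the most ramified classes (maximizing process area relative to
soma), and applies the DEG rule to process-versus-soma. Tau specificity
is sum(1 − x_i/max x)/(N − 1); genes are target-specific at subclass
tau ≥ 0.85 with the target as argmax, and ubiquitous below 0.80 at both
class and subclass level. Gene-set scores subtract expression-matched
controls drawn from 25 mean-expression bins (50 controls per set gene,
seeded); this binned-control scheme assumes a panel large enough that a
bin holds many genes — with tiny panels a set gene can dominate its own
bin and the score degenerates toward zero.

## Morphology-expression correlation and classification

Spearman correlations for every gene-feature pair are computed on a
seeded 75% training split only; the held-out 25% is reserved for
clustering and never influences gene selection. Top-k selection ranks
by |rho| (the choice of sign is genuinely open; signed ranking
is available via a flag) and unions the top 5 per feature. Held-out
validation clusters the gene-set expression with average-linkage
hierarchical clustering cut at two groups and scores agreement against
the amoeboid (C1–C2) versus ramified (C3–C5) partition with the
adjusted Rand index. The shape classifier is a random forest on
whole-cell normalized expression of process-enriched genes, an 80/20
stratified seeded split, and a small fixed hyperparameter grid (trees
in {100, 300}, depth in {None, 10}) tuned by 3-fold cross-validated
accuracy on the training split; performance is held-out AUROC and
mean-decrease-in-impurity importances.

## Spatial statistics

**Ripley.** K(r) = V/(n(n−1)) Σ 1[d_ij ≤ r] in three dimensions with
no edge correction: the Monte-Carlo null redraws the same number of
molecules uniformly over the *same* compartment voxel set, so boundary
bias cancels in the comparison. H(r) = (3K/(4π))^(1/3) − r is the 3D
Besag-style variance stabilization, zero-centered under complete
spatial randomness. Envelopes are pointwise order-statistic quantiles
(5% "lower", 95% "higher") of the null H curves: with B null draws the
exchangeable-rank probability of a CSR pattern landing outside the band
is ≈ 10%, which the calibration benchmark verifies. For process
compartments the statistic is computed within each connected process
individually and averaged. The statistic is effectively continuous only
when expected pair counts are not tiny; at radii far below the
inter-molecule spacing, tied small counts make the test conservative.

**Co-localization.** The radius is the 5th percentile
(linear-interpolation) of pooled 3D pairwise distances between soma
molecules. Per cell and compartment, close pairs of *distinct* genes
within the radius are counted (same-gene pairs excluded); the null
redraws every molecule uniformly within its own compartment, preserving
per-gene counts, 1,000 times by default (benchmarks use 200). Per cell,
z = (observed − null mean)/null sd with a one-sided upper p (excess
contact is the hypothesis); across cells, counts and z are averaged per
pair and p is recomputed from the averaged z — the literal
"average the statistical measures" reading; a Stouffer-style
combination would weight cells by sqrt(n) instead and is a one-line
change. Edges require BH-adjusted p < 0.05, observation (count ≥ 1) in
at least 4 cells, and an average count at or above the 90th percentile
of non-zero average null contacts, applied conjunctively; connected
components of ≤ 2 genes are dropped. Surviving components are clustered
with a Gaussian mixture on their z-weighted adjacency rows, component
count chosen by BIC over k = 1 … min(5, nodes), seeded — a reproducible
replacement for manual cluster-count choice.

## The synthetic-data generator

The generator plants every effect the analysis stages are meant to
detect, so recovery can be scored against a serialized truth manifest
that regenerates the dataset bit-exactly from its seed.

- **Shapes.** A soma disk plus branches grown from the soma rim by a
  biased random walk (unit steps, wrapped-Gaussian heading jitter set by
  the tortuosity parameter, one optional secondary branch with
  probability 0.3 at midpoints), dilated to the branch width. The 2D
  shape is replicated across 6 planes with independent boundary erosion
  noise per plane, emulating plane-to-plane segmentation jitter in thin
  sections; the package analyzes maximum projections, so no true 3D
  arbor geometry is modeled. Ramified cells default to 5 primary
  branches of mean length 60 px; amoeboid cells to a larger soma with 2
  stubby branches (real amoeboid microglia retain short protrusions,
  and an all-soma cell could host no process-assigned molecules).
- **Transcripts.** Per gene, molecule count ~ Poisson(mean 30 per cell,
  a realistic per-gene MERFISH yield); compartment by
  Bernoulli(sigmoid(process log-odds)); placement uniform over the
  compartment's voxels, or a Thomas process (parents uniform in the
  compartment, children isotropic Gaussian sd 1 um, redrawn when
  outside the mask) when clustering is planted. Planted co-localized
  pairs share their partner's cluster parents. Astrocyte contamination
  is a GFAP disk overlapping a set fraction of process pixels, carrying
  its own genes, to exercise GFAP subtraction.
- **Age effect.** Aging multiplies |process log-odds| by an attenuation
  in [0, 1] and retains ceil(fraction × P) of the P planted pairs, in
  panel order — a controlled analogue of reduced compartmentalization
  and sparser co-localization networks in aged tissue.

What the generator does *not* emulate: microscope PSF and noise,
true 3D arbors, cell-to-cell contact, panel-wide expression
correlation structure, or segmentation errors beyond boundary jitter.
Passing benchmarks therefore demonstrates correctness of the
statistical machinery under its stated model, not performance on real
tissue.

## Benchmark problem sizes

The benchmark module fixes the scenario sizes: Ripley calibration uses
500 CSR genes of 80 molecules in a soma-sized compartment with 200 null
draws (pair counts at radii 1–2 um are then large enough that the
envelope test is near-exact); Thomas power uses 100 runs at sigma 1 um
with 10 children per parent; co-localization uses 20 planted and 20 CSR
datasets of 50 cells at 200 randomizations; enrichment uses 200
ramified cells with ±2 log-odds planted against 20 neutral genes; the
classifier uses 200 cells per class with 4-fold planted differences and
20 label permutations. A full benchmark run completes in about five
minutes on one CPU.

## Known limitations

- GFAP subtraction cannot remove astrocyte molecules outside
  GFAP-positive pixels; the generator's blob model is the easy case.
- The handcrafted embedding captures multiscale gradient structure but
  is not a learned representation; cluster boundaries on real data
  would differ from a CNN backend even though the interface contract is
  identical.
- Averaging z across cells treats cells as exchangeable; cells with few
  molecules contribute as much as dense cells.
- The Ripley estimator omits edge correction by design; its absolute
  K values are biased near boundaries and only envelope-relative flags
  should be interpreted.
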