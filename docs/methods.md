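# Methods

This note documents the models and procedures `scarst` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## The synthetic lesion generator

### Lattice

Spots are hexagonally packed: odd array rows are offset by half a pitch and
rows are spaced `pitch·√3/2`, so every interior spot has six equidistant
neighbors at exactly one pitch. Defaults mirror the vendor capture array:
78 × 64 = 4,992 spots, 100 µm pitch, 55 µm spot diameter, a ~6.5 mm square.
Coordinates use the image convention (origin at the top-left spot, y
increasing downward); `array_row`/`array_col` are 0-based.

### Scenes

A scene is one time point of a lesion: concentric rings centered at the
lattice center. At 3 dpi the core is macrophage-dominated; from 7 dpi on it
is fibroblast-dominated, wrapped by microglial and astrocytic rings, an
oligodendrocyte band, and neurons outside. Ring outer radii (µm) per dpi are
configuration, not measurements — the core shrinks from 7 to 28 dpi to mimic
scar compaction:

| dpi | core | microglia | astrocyte | oligodendrocyte |
|----:|-----:|----------:|----------:|----------------:|
|   3 |  700 (macrophage) | 1000 | 1400 | 2000 |
|   7 |  600 (fibroblast) | 1000 | 1400 | 2000 |
|  14 |  500 (fibroblast) |  900 | 1300 | 1900 |
|  28 |  400 (fibroblast) |  800 | 1200 | 1800 |

Per-spot cell counts are uniform on {1..6}, the DAPI-observed range.

**Mixture model.** Each spot's composition is dominated by its ring's cell
type; shares of the radially adjacent types decay as a Gaussian of the
spot-center's distance to the ring edge with scale equal to the spot radius
(27.5 µm). The rationale is geometric: a 55-µm spot on a 100-µm pitch only
captures a mixture when its footprint actually straddles a domain boundary,
so spots one pitch or more from an edge are nearly pure while straddling
spots approach a 50/50 split. Shares are capped at 0.49 (times a per-spot
random damping in [0.7, 1.0]), which guarantees the mixture's argmax is
always the ring label — the ground-truth labels downstream recovery is
scored against.

### Counts

Counts are negative-binomial via a gamma–Poisson mixture. Cells in a spot
are allocated to types multinomially from the spot mixture; for `n` cells of
one type, each gene contributes `NB(mean = n·µ_g, size = n·φ)` (the sum of
`n` i.i.d. per-cell draws). Defaults: baseline `µ = 0.3` per cell per gene,
dispersion `φ = 2`, marker genes up-weighted by `e^2.2 ≈ 9×` in their own
type. These put the median spot at a few hundred UMIs over a 300–400-gene
panel — scaled down from a transcriptome-wide run but with the same
per-gene signal-to-noise regime. Planted ligand–receptor effects add a
constant (default 3.0) to the per-cell mean of the ligand in its source type
and the receptor in its target type. All draws flow from a single seed
through `numpy.random.SeedSequence`, so every generator output is a pure
function of (inputs, seed).

**What the generator does not emulate:** segmentation error and doublets,
spatial autocorrelation of depth, batch and section effects, bleed-through
between spots, zero-inflation beyond NB, anatomically realistic (non-annular)
domain shapes, and transcriptome-wide gene panels. Tests passing on these
scenes therefore demonstrate correctness of the statistics under a clean
generative model, not robustness to every artifact of real sections.

## Preprocessing

- **QC**: a spot is retained iff its total UMI count is ≥ 163. The threshold
  is the study's stated per-spot UMI criterion, read as a retention filter
  (the standard reading for spot arrays).
- **Normalization**: `Ei = log(UMI + 1)` with the natural log; no library
  scaling, matching the stated formula. The sparsity pattern is preserved
  exactly.
- **HVGs**: plain per-gene variance of `Ei` across spots (population
  variance), descending, ties broken lexicographically by gene name. Top
  2,000 by default.
- **Domain labeling**: external labels are the first-class input. The
  built-in labeler is plumbing: PCA of the (HVG-restricted) spot profiles to
  30 components, then k-means (10 restarts, seeded). Each spot profile is
  centered on its own mean before PCA — with 1–6 cells per spot, per-spot
  depth varies several-fold and otherwise dominates the leading component,
  masking cell-type structure. This labeler deliberately replaces graph-based
  clustering and is not a reproduction of it.

## Signature scoring

**Module score** (used for cell-type assignment): genes are binned into 25
equal-count bins of average expression (average ranks, so genes with tied
averages — e.g. all-zero genes — share a bin); each signature gene draws up
to 100 control genes from its bin without replacement (signature genes
excluded); the score is the mean signature `Ei` minus the mean control `Ei`
per spot. Because controls are expression-matched, the score is invariant to
adding a constant to the whole matrix, and a constant matrix scores 0.
Each cluster is assigned the cell type with the highest mean score over its
spots; ties break by cell-type name with a logged warning.

**Pathway activity**: a single-sample rank statistic. Within each spot,
genes are ranked by `Ei` (average ranks for ties); the score is
`2·(mean rank of set genes − mean rank of background genes)/G`, the
integrated difference of the two rank ECDFs, identical to `2·AUC − 1` of the
set-vs-background rank classifier. It is bounded in [−1, 1], equals +1 when
the set occupies the top ranks, is antisymmetric under reversal of the
ranking, has mean ≈ 0 for randomly placed sets, and depends only on
within-spot ranks (invariant to any strictly monotone per-spot transform).
This deliberately replaces the kernel-density random-walk enrichment
statistic of the GSVA family: the score is used as a relative spatial
activity map, and the rank-sum statistic preserves that ordering semantics
while being fully specified and exactly testable. Absolute values are not
comparable to GSVA outputs.

**Layer profiles**: the section is cut into `n_layers` equal-width bands
(default 4) perpendicular to the mediolateral axis; within a layer, spots are
binned by signed distance from the scar center along the rostrocaudal axis in
units of one pitch (halves round away from zero, keeping the binning
mirror-symmetric), and the per-bin mean score is reported from −R to +R.

## Scar geometry

The neighbor graph joins spot pairs at exactly one pitch (±1 nm tolerance).
The scar center is the centroid of scar-labeled spots (the construction is
not otherwise specified in the source analysis); the scar radius is the
maximum center-to-spot distance, also expressed in spots as
`ceil(radius/pitch)` — 1.2 mm at 100 µm pitch is 12 spots. Interface bands
("2 spots wide") are defined by lattice-graph step distance: the spots of
cluster A within `width` BFS steps of any spot of cluster B, and vice versa.
Step distance, not Euclidean distance, is used because the band is counted
in spots. Non-adjacent clusters yield an empty region, not an error.

## Boundary ligand–receptor test

For every ordered pair of adjacent domains (both directions are reported),
candidate pairs are tested on the interface bands:

1. **Filter**: ligand expressed (`Ei > 0`, i.e. ≥ 1 UMI) in strictly more
   than `threshold` (default 0.1) of ligand-side spots, and likewise the
   receptor on the receptor side. Filtered-out pairs are reported without a
   p-value.
2. **Score**: `(mean Ei(ligand) over the ligand side + mean Ei(receptor)
   over the receptor side)/2` — the mean of the two cluster averages.
3. **p-value**: labels are shuffled uniformly over the pooled interface
   spots preserving group sizes (default 1,000 permutations); p is the plain
   proportion of permuted scores ≥ the observed score, so p = 0 is
   attainable; the conservative `(k+1)/(n+1)` estimate is reported alongside.
   Equality is tested with a relative tolerance of 1e−9 so that a constant
   gene yields exactly p = 1 regardless of floating-point summation order.

The permutation universe is the interface spots (the statistic's support);
shuffling whole clusters instead is available via `scope="cluster"`. Under
an exchangeable null the test is calibrated: at 200 independent pairs,
n_perm = 1,000, the measured fraction of p ≤ 0.05 is ~0.05 (binomial noise
±0.015). Multi-subunit receptor complexes and multiple-testing correction
are out of scope; p-values are reported raw, dot-plot style.

## Co-expression modules

Pearson correlation is computed across spots for the HVGs; zero-variance
genes are flagged and set to correlation 0 against all others (diagonal 1).
k-means (default k = 18, 10 restarts, seeded) runs on the **rows of the
correlation matrix**, so genes cluster by whom they correlate with; module
ids are 1-based in decreasing size order. Clustering raw expression profiles
instead is possible by passing them directly. k is a free parameter, not an
estimate. Submodules come from average-linkage hierarchical clustering on
`1 − r` within a module, cut at 0.5 by default, labeled `<module>.<j>` in
size order. The weighted-network (soft-threshold/TOM) family of co-expression
analysis is intentionally not implemented here.

## Problem sizes and determinism

The test and validation suites run on scaled-down scenes — 30×30-spot
lattices and 200–400-gene panels for recovery and power checks, the full
4,992-spot array where the claim is about the array itself (spot count,
cell-count bounds, geometry) — sizes at which planted effects are
recoverable and every check completes in seconds. Benchmarks: domain-label
recovery is checked on a strong-marker scene (marker fold `e^3.5 ≈ 33×`,
typical of strong lineage markers) where PCA + k-means reaches ARI ≈ 0.86–
0.89 against truth — the residual gap to 1 is the irreducible ambiguity of
boundary-straddling mixture spots; module recovery uses 6 planted blocks of
50 genes (within-block r = 0.8, 500 spots). Every stochastic step takes an
explicit seed, and pipeline runs write a manifest with the config hash so a
run is re-derivable from (inputs, config, seed).

## Known limitations

- The built-in labeler is k-means-shaped (convex, similar-size clusters) and
  underperforms on thin annular domains relative to graph clustering on real
  data; supply external labels for serious use.
- The rank pathway score compresses with heavily tied (sparse) spots.
- Layers are equal-width geometric bands, not anatomical boundaries.
- The LR test treats spots, not cells, as the exchangeable unit; with 1–6
  cells per spot this is the natural unit for spot arrays but differs from
  single-cell formulations.
- p-values are Monte-Carlo estimates with resolution 1/n_perm.
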