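# Methods

This note records the model, the parameter choices that matter, the
numerical conventions, and what the synthetic-data generator does and does
not emulate.

## The coarse-graining model

A spatial transcriptomics dataset is a non-negative integer matrix
**X** (genes × spots) with per-spot 2-D coordinates in a single length
unit, optionally with a per-spot categorical annotation. A *metaspot* is a
set of spots that is (a) connected in a spatial neighborhood graph and
(b) chosen to be transcriptomically homogeneous. The *graining level*
γ = n_spots / n_metaspots is the single resolution knob; the *effective* γ
is this ratio after any splitting.

The assumptions are mild but worth stating: spots in physical proximity
are candidates for merging (the method never merges across the spatial
graph), transcriptomic similarity is adequately captured by Euclidean
distance in a low-rank PCA embedding of log-normalized counts, and raw
counts of merged units are additive (true for UMI-type counts; the reason
aggregation sums *raw* counts and re-normalizes afterwards).

### Spatial graph

Each spot is joined to its K nearest neighbors (union symmetrization: an
edge exists if either endpoint selects the other). K defaults encode the
platform geometry: 6 on the Visium hexagonal lattice, 8 on the VisiumHD
square grid (the 8-neighborhood), 15 for irregular imaging point clouds.
Neighbor ties at identical distance are broken by lower spot index, making
the graph deterministic; duplicate coordinates are allowed and produce
length-0 edges.

Pruning removes exactly ⌊F·E⌋ edges of largest Euclidean length (stable
tie order), so F = 0 is an identity. The rationale for a fraction rather
than a length threshold is scale-invariance across platforms. Presets: F =
0.4 on imaging layouts, where sparse tissue regions produce long-range
edges; 0 on near-uniform lattices, where a distance-rank cut would be
arbitrary. Both K and F are overridable (`--k`, `--f-prune`).

### Edge weights

Counts are scaled to 10⁴ per spot and log1p-transformed; spots with zero
total counts cannot be normalized and are dropped up front with their IDs
reported. PCA uses all genes, centered per gene, without unit-variance
scaling — the fewest-assumptions default — with an optional
highly-variable-gene restriction (`n_hvg`) for parity experiments. The
exact SVD solver is used when the smaller matrix dimension is ≤ 500,
otherwise the seeded randomized solver; either way the embedding is
deterministic given the seed. The default of 30 components is the
workflow's standard operating point.

Each retained edge gets weight w = 1 − d/max(d) with d the Euclidean
distance between its endpoints' 30-PC rows. max(d) is taken over the edges
that survive pruning (recomputed after pruning, not before), so weights
always span down to exactly 0 at the most dissimilar retained pair. If
every connected pair coincides in PC space, all weights are set to 1 with
a warning.

### Merge tree and γ-cut

Both agglomeration schemes produce a full merge history (a forest over
communities), so any γ is a cheap replay:

* **walktrap** — communities are compared by their short random-walk
  profiles: P = D⁻¹A on the weighted graph, walk length `steps` (default
  4, the algorithm's canonical choice), profile metric scaled by 1/√d per
  target node. At each step the adjacent pair with the smallest Ward-style
  increase in mean squared profile distance merges. The implementation
  follows the published random-walk definition directly; it keeps dense
  per-community profile vectors, i.e. O(n²) memory, which is comfortable
  up to a few tens of thousands of spots — beyond that, use greedy.
* **greedy** — Clauset–Newman–Moore-style: the adjacent pair with the
  largest weighted-modularity gain merges. Merging continues past the
  modularity maximum so the tree always reaches one community per
  connected component. Greedy agglomeration is a heuristic: its 2-cluster
  cut agrees exactly with igraph's reference fastgreedy implementation but
  neither is guaranteed to find the globally modularity-optimal
  bipartition.

Shared conventions: merges only join communities connected by at least one
retained edge, which guarantees every cut is spatially connected.
Zero-weight edges count for this adjacency but carry zero random-walk
probability / zero modularity weight, so they are operationally equivalent
to absence for the merge *order*. All tie-breaks are by lowest community
index; there is no randomness in clustering.

The cut rule is n* = max(n_components, round_half_up(n_leaves/γ)): γ = 1
is the identity partition, 3639 spots at γ = 4 give exactly 910 metaspots,
and a graph shattered into more components than round(n/γ) clamps with a
logged warning (isolated nodes pass through every cut as singletons).

### Splitting

With an annotation (missing labels become the reserved category
"Unknown", treated like any other), metaspots are first split per label
category, then any piece that is disconnected in the spatial graph is
split into its components. "The spatial graph" here defaults to the pruned
graph used for clustering — consistent with the coherence guarantee the
clustering already provides — with `--split-graph unpruned` for the
alternative reading. Both splits are idempotent refinements: purity is
exactly 1 afterwards, every metaspot induces a connected subgraph, and the
effective γ never increases.

### Metrics

* purity: modal-label fraction per metaspot.
* ARI: pair-counting adjusted Rand index (computed via the pair confusion
  matrix); in the degenerate case where the chance-corrected denominator
  vanishes, the result is 1 when the partitions agree on every pair and 0
  otherwise.
* sparsity: per-unit detected (nonzero) gene counts and overall nonzero
  fraction.
* max intra-metaspot distance: exact all-pairs maximum per metaspot, 0 for
  singletons.
* proportion variability: given per-spot cell-type proportion vectors, the
  size-weighted mean over metaspots (size ≥ 2) of the per-celltype sample
  standard deviation (ddof = 1) averaged over cell types. The null
  distribution repeats the statistic on `n_random` (default 100) random
  partitions preserving the metaspot size multiset, seeded. This
  particular statistic is a design choice — other dispersion summaries
  would serve — and is documented so comparisons are well-defined.

## Synthetic data generator

`synthdata` emulates three platform layouts with unit pitch: a row-offset
hexagonal lattice (interior spots have 6 equidistant neighbors at distance
1), a square grid, and a uniform-density point cloud, optionally with a
vertical strip at 5% ambient density (`gap_width`) to create the
long-range KNN edges that F-pruning targets. Domains are spatially
contiguous: equal-count horizontal bands on lattices (cortex-layer-like)
or Voronoi cells of randomly seeded spots on point clouds; every domain is
non-empty by construction.

Counts are negative-binomial (gamma–Poisson), the standard overdispersion
model for UMI counts: gene baselines are lognormal (σ = 1), each domain's
marker block is raised by exactly `marker_fold`, and a single global scale
sets the mean expected library to `library_mean` (per-domain libraries
then vary by a few percent, as in tissue). Defaults — 3639 spots, 7
domains, 500 genes, 20 markers/domain, fold 4, dispersion 0.5, library 100
— put the spot-level matrix at ≈ 87% zeros, inside the 80–95% regime
typical of both sequencing- and imaging-based platforms, with domains that
are recoverable but not trivially separable (metaspot purity ≈ 0.96 at
γ = 4, not 1.0). Everything is deterministic given the config seed, with
an independent substream per stage.

What the generator does *not* emulate: transcriptome-wide co-expression
structure, segmentation artifacts, cell-density gradients within domains,
platform-specific capture biases, or histology. Tests passing on these
fixtures therefore demonstrate the algorithmic contracts (conservation,
connectivity, determinism, monotonicity, recovery of well-separated
contiguous domains) — not performance on real tissue.

## Numerical choices and degenerate inputs

* round-half-up for the γ → cluster-count rule (2.5 → 3), clamped below by
  the component count.
* Nodes whose incident weights are all zero are absorbing states of the
  random walk (P_ii = 1) and use d = 1 in the profile metric.
* A graph with zero edges yields a tree with no merges; every cut is all
  singletons.
* Counts are stored column-compressed; densification (needed for PCA) is
  refused above 10⁸ entries.
* Metaspot centroids are serialized with 18 significant digits and parsed
  with round-trip float precision, so write → read is bit-exact.
* Problem sizes in the test suite (3639-spot lattice for end-to-end runs,
  ≤ 1000-spot clouds elsewhere) are chosen so the whole suite runs in
  seconds while still exercising the headline arithmetic at the worked
  dataset size.

## Known limitations

* Walktrap memory is O(n²); the greedy path is the intended route for
  VisiumHD-scale data.
* The achievable γ under purity splitting is bounded by the spatial
  mixing of annotations: finely interleaved cell types force many small,
  pure metaspots (effective γ well below the requested one).
* ARI comparisons against external clustering tools, deconvolution-based
  proportions, variance-stabilizing normalization and image integration
  are out of scope; the metrics module only consumes partitions,
  proportions and matrices produced elsewhere.
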