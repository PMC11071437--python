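# Methods

## Model

`nichetraj` treats a tissue section as a graph of overlapping cellular
neighbourhoods and learns a one-dimensional coordinate system over
them. The assumptions are:

- **Niches are local and anchored.** Every cell anchors exactly one
  niche consisting of itself plus its `k_neighbors` nearest neighbours
  (anchor + k members). The anchor's association weight is exactly 1
  (distance 0); other members decay as exp(−d²/σ_j²) with the
  niche-specific scale σ_j equal to the anchor's distance to its
  `sigma_index`-th neighbour. This makes σ data-adaptive: dense regions
  get small kernels, sparse regions large ones, and coordinates never
  need unit conversion.
- **Composition is the niche feature.** Each niche is the
  weight-fraction vector of the M cell types among its members
  (row-stochastic by construction). Spatially adjacent niches share
  most members, so compositions vary continuously over the niche graph
  provided k is large enough — the premise that makes a graph
  smoothness prior sensible.
- **The trajectory is unbranched.** The method orders K soft niche
  clusters along a single chain; branching topologies are out of scope.

### Graph encoder and pooling

The niche graph uses mutual k-nearest-neighbour adjacency ("i in j's
kNN and vice versa"), read as mutual *k*-nearest rather than mutual
rank-1 (rank-1 mutuality would leave the graph nearly edgeless). The
encoder is a two-layer graph convolution X_t = SeLU((Ã + I) X_{t−1} W_t)
with the standard symmetric normalisation Ã = D^{−1/2} A D^{−1/2}
(D the degree matrix). Self-loops are added *after* normalisation,
exactly as the composed formula dictates; the alternative
"renormalisation trick" (normalising A + I) is deliberately not used.
Isolated niches have zero rows in Ã but still propagate their own
features through the +I term. SeLU uses the standard published
constants (α ≈ 1.6733, λ ≈ 1.0507).

The pooling head C = softmax(β X₂ W_c) is deliberately
low-temperature (β = 0.03): assignments start near-uniform and
sharpen only as the trained logits grow, which stabilises the early
epochs of training.

### Loss

- **Modularity** L_m = −Tr(CᵀBC)/(2N), B = A − ddᵀ/(2N). The
  denominators use 2N (the niche count), not the conventional 2m (edge
  count); this follows the method's printed definition and only
  rescales the term — the λ weights absorb the difference. L_m can be
  large and positive under this convention (the degree-product null
  dominates when average degree exceeds 2); only its gradient matters.
- **Purity** L_p: mean squared error, over all N×M entries, between
  each niche's composition and its reconstruction Σ_k c_jk v*_k from
  the cluster centroids. Centroids are *soft* (C-weighted) means,
  keeping the loss differentiable end to end; a cluster whose total
  soft mass falls below 1e−12 has its centroid pinned to the global
  mean composition (treated as constant in the gradient) so degenerate
  clusters cannot produce 0/0.
- **Collapse regulariser** L_r = (K/(N(K−1))) Σ c², bounded in
  [1/(K−1), K/(K−1)]; minimised by the uniform assignment, maximised
  by one-hot assignments.

Weights λ_m = 0.3, λ_p = 300, λ_r = 0.1. The purity weight dominates by
design: composition homogeneity is the primary clustering signal, with
modularity acting as a spatial-coherence prior.

### Training

The model (W₁: M×H, W₂: H×H, W_c: H×K — a few dozen parameters at the
default H = 4) is implemented directly in numpy with hand-derived
analytic backpropagation through the softmax, both SeLU layers and all
three loss terms, including the dependence of the purity centroids on
C. Gradients are verified against central finite differences (relative
error < 1e−4) in the test suite. Optimisation uses Adam (lr = 0.03,
β₁ = 0.9, β₂ = 0.999) for at most 1000 epochs; training stops early
once the total loss has failed to improve by more than 1e−6 for 50
consecutive epochs (both configurable — an explicit stopping rule
chosen here since only the epoch cap is prescribed). Initialisation is
Glorot-uniform from the run seed; runs are bit-reproducible given the
seed.

Multi-sample inputs train a *common* model: each sample yields its own
niche graph (no edges across samples — coordinates are not comparable
between slices), per-graph losses are averaged within a batch (default
batch size min(n_samples, 10)), and the cluster graph aggregates the
block-diagonal union of all per-sample adjacencies.

### Trajectory construction

Cluster connectivity E = CᵀAC is normalised entrywise by the product
of row and column marginals. The ordering maximising the chained
connectivity is found exhaustively over the K!/2 reversal classes for
K ≤ 9; above that, by multi-start greedy chain extension refined with
an iterated local search (2-opt reversals, or-opt segment relocations
of length 1–3 in both orientations, deterministic double-bridge
perturbations). The tests check the heuristic attains the exhaustive
optimum on random instances. Clusters with zero connectivity marginals
are appended at the end of the ordering so they cannot poison the chain
search. Orientation is canonicalised (first cluster index < last);
since the two directions are equivalent, evaluation against any ground
truth maximises over both, and users can flip with `--reverse`.

Cluster k at position m scores (m−1)/(K−1); niche scores are the
C-weighted averages of cluster scores and cell scores the
w-weighted averages over containing niches, so all scores are convex
combinations inside [0, 1] and reversal maps s → 1 − s exactly.

## Synthetic benchmark generator

The generator emulates a two-lineage differentiation benchmark:
1,000 cells, 10 types (A–J), two lineages from one bifurcation.
Simulated times are drawn Uniform(0, 1) as a surrogate for an external
kinetic simulator's trajectory positions — only the joint structure of
(type, x, y) matters to the method, not the time marginal. Types bin
the time axis equally: 7 bins (A–G) for lineage 1, 3 bins (H–J) for
lineage 2. The lineage split is 7:3 (proportional to type counts; the
source design does not state a ratio), configurable. Lineage-1 cells
are placed on circles of radius t/max(t) at uniform angles (max radius
exactly 1); lineage-2 cells are area-uniform in the unit disk. The
ground truth coordinate is the radius for every cell.

The optional 135-gene count matrix (35 TFs, 50 targets, 50
housekeeping) is a cosmetic surrogate: negative-binomial counts around
means that drift linearly with time in the gene's active lineage
(housekeeping means are flat). It exists so downstream demos mirror the
benchmark's data shape; the core method never reads it, and no claim is
made that it reproduces any kinetic model.

**What passing tests show.** The benchmark has clean segmentation, a
single section, exact type labels, isotropic geometry and types that
partition the trajectory axis. Passing it demonstrates the machinery —
niche construction, training, ordering, scoring — recovers a known
spatial gradient under label noise from a spatially random
subpopulation (lineage 2, 30% of cells). It does not establish
robustness to segmentation errors, annotation noise, anisotropic or
multi-domain tissue, or batch effects in real data.

## Numerical choices

- kNN distance ties break toward the smaller cell index
  (deterministic across platforms).
- σ_j = 0 (at least `sigma_index` coincident points) falls back to the
  smallest positive neighbour distance; an all-coincident niche is an
  error.
- Composition rows are validated to sum to 1 within 1e−9.
- Ordering-search ties: the exhaustive search scans reversal classes in
  lexicographic order and keeps the first maximum; orientation is
  canonical (first index < last).
- Default K = 6 when unset; K is the main user-facing knob and should
  match the expected number of distinct microenvironment zones.

## Problem sizes

Tests run the full 1,000-cell benchmark at three seeds plus a 300-cell
instance shared across unit tests; a full default fit takes roughly two
seconds on one CPU, so the whole suite runs in well under a minute. The
acceptance script runs one full default fit.

## Known limitations

- Unbranched trajectories only.
- No vendor-format readers; inputs are pre-exported cell tables.
- The 2N modularity convention means reported L_m values are not
  comparable to standard modularity scores.
- The expression surrogate is not a kinetic simulation.
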