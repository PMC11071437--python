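# nichetraj

Niche-trajectory construction for spatial omics data at single-cell
resolution.

Tissues are organised as a continuum of local microenvironments
("niches"): spatially localised multicellular regions whose cell-type
mixtures change gradually across space. `nichetraj` orders these
microenvironments along a one-dimensional **niche trajectory (NT)** and
assigns every niche and every cell a coordinate in [0, 1] — the **NT
score** — using only cell positions and cell-type labels. No expression
matrix is required, which distinguishes the approach from pseudotime
methods that order cells by expression and break down when cell types
are spatially scrambled.

It is intended for spatial transcriptomics data (MERFISH, stereo-seq
and similar) that has already been segmented and annotated into a
per-cell table of `cell_id, sample, x, y, cell_type`.

## Method

1. **Niche network.** Each cell anchors one niche containing its *k*
   nearest neighbours (default *k* = 50). Niches are connected when
   their anchors are mutual k-nearest neighbours, giving a binary
   adjacency A = (a_ij). A cell *i* in niche *j* gets the association
   weight w_ij = exp(−d_ij²/σ_j²), with σ_j the distance from the
   anchor to its 20th nearest neighbour, and each niche is summarised by
   its weighted cell-type composition v_jm = Σ_i w_ij I_im / Σ_i w_ij.
2. **Graph convolutional encoding.** A two-layer GCN,
   X_t = SeLU((Ã + I) X_{t−1} W_t) with Ã = D^{−1/2} A D^{−1/2} and
   X_0 = V, embeds every niche in 4 dimensions (default).
3. **Soft graph pooling.** C = softmax(β X_2 W_c) assigns niches
   probabilistically to K clusters (default K = 6, β = 0.03). The
   parameters are trained with Adam (lr = 0.03, ≤ 1000 epochs) on
   L_total = λ_m·L_m + λ_p·L_p + λ_r·L_r with λ_m = 0.3, λ_p = 300,
   λ_r = 0.1: L_m = −Tr(CᵀBC)/2N negates modularity
   (B = A − ddᵀ/2N), L_p penalises the mean squared error between
   each composition and its soft-cluster-mean reconstruction, and
   L_r = (K/(N(K−1))) Σ c_jk² discourages collapsed clusterings.
4. **Trajectory.** The niche network is collapsed to a cluster graph
   E_kl = Σ_ij c_ik a_ij c_jl, normalised to Ẽ; the cluster ordering
   p_1…p_K maximising Σ_k Ẽ_{p_k,p_{k+1}} is found (exhaustively for
   K ≤ 9, by iterated local search above). Cluster p_k gets the score
   (k−1)/(K−1); niche scores are s_j = Σ_k c_jk s_k and cell scores
   s̃_i = Σ_j w_ij s_j / Σ_j w_ij.

The direction of a 1-D trajectory is inherently ambiguous; reversing it
maps every score s → 1 − s (`--reverse`, or `results.reverse()`).

## Worked example

The built-in generator reproduces a standard synthetic benchmark:
1,000 cells from 10 types (A–J) in two lineages diverging at a
bifurcation; lineage-1 cells (types A–G) sit on circles whose radius is
their rescaled simulated time, so space encodes their trajectory
radially, while lineage-2 cells (H–J) are scattered uniformly in the
unit disk and carry no spatial signal. The ground-truth coordinate of
every cell is its radius.

```python
from nichetraj import NicheTrajectory, simulate_dataset, spearman_aligned

data = simulate_dataset(seed=0)                    # 1,000 cells, 10 types
model = NicheTrajectory.from_dataframe(data.cells)  # defaults as above
res = model.fit()
print(res.summary())
rho, flipped = spearman_aligned(res.cell_scores, data.ground_truth)
print(f"aligned Spearman vs ground truth: {rho:.3f}")
```

prints

```
Niche Trajectory Results
============================================================
cells: 1000   samples: 1   cell types: 10   clusters: 6
epochs run: 1000   final loss: 19.156614 (L_m=59.2635, L_p=0.004249, L_r=1.0277)
cluster ordering: 0 -> 1 -> 4 -> 5 -> 3 -> 2

 cluster   score  soft size
       0   0.000      123.4
       1   0.200      167.7
       4   0.400      165.5
       5   0.600      165.0
       3   0.800      172.2
       2   1.000      206.2

cell NT scores: min=0.000  median=0.595  max=1.000

aligned Spearman vs ground truth: 0.986
```

The six clusters form concentric rings; the chained ordering runs from
the disk centre outward, and cell-level NT scores track the true radial
coordinate with Spearman ρ ≈ 0.95–0.99 depending on the seed — even
though 30% of the cells (lineage 2) have spatially uninformative type
labels. `res.plot_spatial()` and `res.plot_density()` visualise the
score field and the per-type density along the trajectory;
`res.stratify(cutoff=0.17)` splits cells into NT-Low/NT-High strata and
`nichetraj.reference_depth(cells, "VLMC")` computes median-distance
depth to a landmark population.

The same pipeline runs from the shell:

```bash
nichetraj simulate --output cells.csv --n-cells 1000 --seed 0
nichetraj run --input cells.csv --output results/ --n-clusters 6 --seed 0
```

writing per-cell and per-niche NT scores, cluster probabilities, the
cluster ordering, the loss trace and run metadata as CSV/YAML tables.

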