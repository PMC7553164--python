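# bcd — a batch-corrected distance for longitudinal single-cell data

Clustering and visualization of single-cell RNA-seq data are distance-based,
and the default Euclidean distance does not distinguish biological variation
from batch effects — the systematic technical offsets between separately
processed samples. On longitudinal (or spatial) experiments this is
especially damaging: standard integration methods treat *all* between-sample
differences as nuisance and over-correct, erasing the very developmental
signal a time course exists to measure.

`bcd` implements a **batch-corrected distance (BCD)** that exploits the
*locality* of batch effects: samples collected at the same or adjacent time
points (or neighbouring locations) should look alike, so differences between
them are mostly technical, while differences between distant time points are
mostly biology. Cells are compared with a Mahalanobis-style distance

```
d(x_i, x_j) = sqrt( (x_i − x_j)ᵀ (Σ̃ + ridge·I)⁻¹ (x_i − x_j) )
```

whose covariance is the locality-weighted between-batch scatter

```
Σ̃ = Σ_i Σ_{j : i ∉ C_j}  W_ij (x_i − m_j)(x_i − m_j)ᵀ,
W_ij = exp( −‖τ_i − t_j‖² / 2l² ),
```

where `C_j` are the cells of batch *j*, `m_j` its centroid, `t_j` its label
(a scalar day, or a vector such as `[week, location]`), `τ_i` the label of
cell *i*'s own batch, and `l` the length scale within which batches count as
close. Directions along which *proximal* batches differ dominate Σ̃ and are
suppressed by its inverse; with `W ≡ 1` the construction reduces to the
classical unweighted alternative-clustering metric. The inverse lower
Cholesky factor of Σ̃ + ridge·I whitens the data so that plain Euclidean
distance in the transformed space *is* BCD — which makes the metric a
drop-in for any kNN/graph-clustering/UMAP toolchain. On `k` principal
components the cost is O(nk² + k³).

The package ships the full chain:

- `bcd.metric` — locality weights, Σ̃, whitening, pairwise/kNN BCD;
- `bcd.preprocess` — sum-to-one normalization, variance-stabilized HVG
  selection, gene scaling, PCA;
- `bcd.simulate` — a longitudinal differentiation simulator (tree
  S → {A,B} → {A1,A2,B1,B2}, θ-interpolated intermediate states, per-sample
  additive batch effects on a susceptible gene subset, Poisson counts) with
  ground-truth labels;
- `bcd.downstream` — exact kNN graph, Leiden clustering, UMAP, scoring
  (adjusted Rand index, batch-mixing entropy, silhouette);
- `bcd.pipeline` / `bcd.cli` — the end-to-end runner and the `bcd`
  command-line tool.

## Worked example

Generate the packaged seven-sample benchmark (days 1–4, 500 cells/sample,
200 genes, 50 batch-susceptible genes) and run the pipeline twice — with
BCD whitening and with the plain Euclidean baseline:

```sh
bcd simulate --seed 1 --outdir demo
bcd run --counts demo/matrix.mtx --meta demo/truth.csv \
    --batch sample --labels day --l 1 --n-hvg 150 --n-pcs 30 \
    --seed 1 --outdir demo/bcd_run
bcd run --counts demo/matrix.mtx --meta demo/truth.csv \
    --n-hvg 150 --n-pcs 30 --seed 1 --no-bcd --outdir demo/euclidean_run
```

which prints

```
ARI=0.597 batch_mixing=0.539 silhouette=0.083   # BCD, 7 clusters
ARI=0.545 batch_mixing=0.000 silhouette=0.244   # Euclidean, 21 clusters
```

Read: the Euclidean pipeline fractures the data into 21 clusters — each
terminal cell type splits into one cluster per sample (batch-mixing entropy
≈ 0), and its higher silhouette only reflects that batch effects *are* a
strong cluster structure. BCD recovers 7 clusters matching the biological
populations, mixes same-type cells from different samples, and scores a
higher adjusted Rand index against the true labels. Each run writes
`pca.csv`, `coordinates.csv` (whitened), `clusters.csv`, `embedding.csv`,
`evaluation.json` and a `manifest.json` sufficient to reproduce it.

For data with both temporal and spatial structure, pass several label
columns (`--labels week --labels location`); they are concatenated into one
label vector under a single Euclidean norm. `bcd transform` whitens
precomputed coordinates without rerunning preprocessing, and
`bcd evaluate` scores any clustering against a ground-truth table.

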