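# pseudomst

Cluster-based minimum-spanning-tree pseudotime reconstruction for single-cell
RNA-seq, with a quantitative framework for evaluating cell orderings.

## The problem

Cells sampled from a differentiation or response time course form a continuum
of transcriptional states. *Pseudotime reconstruction* places the cells in an
order reflecting that gradual transition, so downstream analyses can study
gene-expression dynamics along the process. Tree-based orderings built
directly on individual cells are noisy and unstable; this package instead

1. reduces the matrix to a per-cell representation Ẽᵢ (gene-cluster averaging
   to dilute drop-out events, row standardization, PCA with a scree-breakpoint
   rule for the number of components K),
2. clusters cells by a full-covariance Gaussian mixture (model count chosen by
   BIC = 2 log L − p log N),
3. connects the cluster centers by a **minimum spanning tree** under Euclidean
   edge lengths, takes the leaf-to-leaf path with the most clusters (ties: most
   cells) as the main path, and
4. projects each cell k onto its nearest path edge (Cᵢ, Cⱼ) by the scalar
   vᵢⱼᵀ Ẽₖ / ‖vᵢⱼ‖ with vᵢⱼ the edge vector; the k-th ordered cell gets
   integer pseudotime k.

Genes changing along the ordering are detected by a likelihood-ratio test of a
3-df natural-spline trend model against a constant model, with
Benjamini–Hochberg FDR control.

Ordering quality is measured by the **pseudo-temporal ordering score**
(POS: normalized sum of signed pairwise collection-time differences,
1 = perfect agreement, −1 = exact reversal), the **ordering similarity score**
(fraction of unordered cell pairs with preserved relative order, missing cells
counted discordant), perturbation **robustness** (cell subsampling or
permuted-residual expression noise, 100 replicates), and **gold-gene rank**
metrics for differential-expression rankings.

Everything is exercisable on synthetic data: the built-in generator simulates
trajectories with known latent pseudotime, branch structure, collection-time
bins, trend genes and dropout.

## Worked example

```python
import pseudomst as pm

cfg = pm.TrajectoryConfig(n_cells=300, trend_shapes=("linear",), seed=11)
m, truth = pm.simulate_trajectory(cfg)           # 500 genes, 100 with a trend
marker = truth.trend_genes[0]                    # orient the path by a marker
res = pm.run_pipeline(m, pm.RunConfig(seed=1, marker_gene=marker))

print("clusters:", res.model.n_clusters)
print("retained PCs:", res.reduced.k)
print("main path:", "-".join(map(str, res.main_path.cluster_sequence)))
print("POS vs collection time:", round(res.report.pos, 4))
print("differential genes (FDR<0.05):", res.de.n_differential())

labels = pm.TimeLabels.from_matrix(m)
baseline = pm.marker_only_ordering(m, marker, "increasing")
print("marker-only baseline POS:",
      round(pm.pos_score(baseline.cell_order, labels), 4))
```

prints

```
clusters: 2
retained PCs: 2
main path: 2-1
POS vs collection time: 0.9514
differential genes (FDR<0.05): 110
marker-only baseline POS: 0.6149
```

The tree ordering tracks the (held-out) collection-time bins far better
(POS 0.95) than sorting cells by a single noisy marker gene (POS 0.61),
because gene-cluster averaging and PCA pool the signal of all 100 trend genes.
110 genes are flagged differential at FDR < 0.05 — roughly the 100 simulated
trend genes plus the expected handful of false positives — and the top of the
ranking is made up of true trend genes.

## Command line

```sh
pseudomst simulate --n-cells 300 --seed 11 --out-prefix sim/run1
pseudomst run --input sim/run1.expr.tsv --time sim/run1.time.tsv \
    --marker g0001 --seed 1 --outdir out/
pseudomst evaluate --ordering out/ordering_main.tsv --time sim/run1.time.tsv
```

`run` writes the per-path ordering tables (cell_id, cluster, edge, projection,
pseudotime), the tree as JSON, the differential-expression table, the scree
table, an evaluation report, and a manifest recording the full configuration
and seed. `preprocess`, `order`, `diffexpr` and `evaluate` expose the
individual stages.

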