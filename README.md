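# progclust

Progressive tree-structured clustering of scRNA-seq data that resolves
**abundant and rare cell populations simultaneously**.

Unbalanced single-cell data mixes populations of thousands of cells with
populations of a handful.  Methods tuned for abundant structure (variance-
based gene selection, k-means) absorb rare cells into big clusters;
methods tuned for rare cells (global Gini-index gene selection) cannot
resolve abundant structure.  `progclust` runs both detectors *locally*
while growing divisive clustering trees:

* **Fano-based clustering** at each tree node: the top-1000 genes by Fano
  factor `Fano_i = var(g_i)/mean(g_i)` span the node's feature space
  (merged with the parent's genes to prevent over-clustering); nodes with
  more than 50 cells are clustered by PCA + k-means with k chosen by the
  gap statistic, smaller nodes by spectral clustering on cosine
  similarity, growing k until the similarity gain
  `S_k^{k+1} = max_m r_m^{k+1}` (the best relative increase in
  intra-cluster similarity) drops below `ic = 0.12`.
* **Gini-based rare detection** at each node: locally high normalized-Gini
  genes define a rare subspace; cells with total expression below a noise
  threshold (30 on counts) stay abundant; the rest are partitioned by
  Affinity Propagation, and subclusters with outlier score
  `I_m / O_m > ros = 3.5` (mean within-similarity over mean similarity to
  the rest of the node) are shed as rare.
* **Round 2**: all shed cells are pooled and clustered by a second tree of
  the same design, yielding the rare clusters.

The package also provides the matching **weighted evaluation metrics**
(every cell weighted by the reciprocal of its reference class size, so a
3-cell class counts as much as a 2000-cell one), a **rare-cluster
recall/precision protocol**, and an **unbalanced synthetic-data
generator** with the four study compositions built in.

## Worked example

```python
import progclust as pc

m, truth = pc.generate(pc.table1_preset("sim1", seed=0))
assignment, tree1, tree2 = pc.run_progclust(m, pc.ProgClustConfig(seed=0))
pred = assignment.labels()
print(pc.weighted_nmi(pred, truth), pc.weighted_purity(pred, truth))
```

Running `python examples/cluster_unbalanced_mixture.py` (the same
computation with a composition report) prints:

```
generated 2000 genes x 3023 cells, cluster sizes [2000, 1000, 10, 6, 4, 3]
found 6 clusters (0 cells via the rare round)
   c1 (r1_1): {'type1': 2000}
   c2 (r1_0): {'type2': 1000}
   c3 (r1_2/1): {'type3': 10}
   c4 (r1_2/2): {'type4': 6}
   c5 (r1_2/0): {'type5': 4}
   c6 (r1_2/3): {'type6': 3}
weighted NMI    = 1.000
weighted Purity = 1.000
```

All six populations are recovered exactly, including the 3-cell one: the
root k-means isolated the two abundant populations and routed the 23
remaining cells into one branch, whose spectral stage separated the four
rare types.  Weighted NMI/Purity of 1.0 mean the predicted partition
matches the reference on every class, with rare classes counted at equal
weight.  `examples/detect_rare_cells.py` shows the rare detector alone —
5 planted cells in a 505-cell cluster surface as one Affinity Propagation
subcluster with outlier score 4.35 > 3.5 and are flagged; the other
examples demonstrate gene scoring and the weighted metrics.

## Command line

```sh
progclust simulate --preset sim1 --seed 0 --outdir data/
progclust run --input data/ --seed 0 --outdir out/
progclust evaluate --assignment out/assignment.tsv --truth data/labels.tsv
```

`run` accepts a 10x Matrix Market triplet directory (v2/v3, plain or
gzip) or a delimited matrix in either orientation, and writes the
assignment table, tree structures as JSON, and display-label mapping.
All pipeline parameters are available via `--config key=value` files and
flags; see `docs/methods.md` for each parameter's meaning and default.

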