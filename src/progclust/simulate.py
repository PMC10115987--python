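"""Unbalanced synthetic scRNA-seq count mixtures with planted clusters.

The generator emulates a read-count-scale matrix (Smart-seq-like, the
regime of negative-binomial fits to real data): per-gene baseline means
drawn log-uniformly over roughly an order of magnitude, NB counts with a
shared mild dispersion, and cluster identity imposed through marker-style
differentially expressed (DE) genes.  A DE gene of cluster k with baseline
mean b is drawn at mean ``b * fold_change`` inside k and
``b / fold_change**2`` outside — markers are high in their population and
near-silent elsewhere (in/out ratio ``fold_change**3``), the structure
that makes them high-Gini within any mixture containing the cluster;
``fold_change = 1`` is an exact null.  Cluster compositions mirror the
four unbalanced presets of the simulation study (e.g. 2000,1000,10,6,4,3),
mixing abundant populations with clusters of only a few cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import ExpressionMatrix

#: cluster compositions of the four simulation presets
TABLE1_PRESETS: dict[str, list[int]] = {
    "sim1": [2000, 1000, 10, 6, 4, 3],
    "sim2": [1000, 1000, 100, 100, 10, 10],
    "sim3": [1500, 1000, 1000, 100, 100, 10],
    "sim4": [1500, 1000, 500, 250, 100, 50],
}


@dataclass
class SimSpec:
    """Composition and effect-size description of one synthetic dataset.

    ``baseline_mean`` is the geometric center of the per-gene baseline
    mean distribution (log-uniform on [baseline_mean/4, 4*baseline_mean]);
    ``dispersion`` is the negative-binomial size parameter (variance =
    mu + mu^2 / dispersion).
    """

    cluster_sizes: list[int]
    n_genes: int = 2000
    n_de_genes_per_cluster: int = 50
    fold_change: float = 8.0
    baseline_mean: float = 2.0
    dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")
        if self.fold_change < 1:
            raise ValueError("fold_change must be at least 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")

    @property
    def n_cells(self) -> int:
        return int(sum(self.cluster_sizes))


def table1_preset(name: str, seed: int = 0, **overrides) -> SimSpec:
    """SimSpec for one of the four named unbalanced compositions."""
    if name not in TABLE1_PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid names: {sorted(TABLE1_PRESETS)}"
        )
    return replace(
        SimSpec(cluster_sizes=list(TABLE1_PRESETS[name]), seed=seed), **overrides
    )


def generate(
    spec: SimSpec, return_means: bool = False
):
    """Draw a count matrix and its reference labels.

    Each cluster owns a disjoint random set of ``n_de_genes_per_cluster``
    marker genes: negative-binomial mean ``b * fold_change`` for the
    cluster's cells and ``b / fold_change**2`` for every other cell (b the
    gene's drawn baseline).  Fully reproducible from ``spec.seed``.  With
    ``return_means`` the genes x cells NB mean matrix is returned as well.
    """
    n_clusters = len(spec.cluster_sizes)
    n_de_total = n_clusters * spec.n_de_genes_per_cluster
    if n_de_total > spec.n_genes:
        raise ValueError(
            f"{n_clusters} clusters x {spec.n_de_genes_per_cluster} DE genes "
            f"exceed {spec.n_genes} genes; disjoint sets impossible"
        )
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.baseline_mean / 4.0, spec.baseline_mean * 4.0
    base_mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_genes))

    de_pool = rng.permutation(spec.n_genes)[:n_de_total]
    de_sets = de_pool.reshape(n_clusters, spec.n_de_genes_per_cluster)

    n_cells = spec.n_cells
    mu = np.tile(base_mu[:, None], (1, n_cells))
    labels_arr = np.empty(n_cells, dtype=object)
    # every DE gene starts at the leak level and is raised in its owner
    f = spec.fold_change
    mu[de_pool, :] /= f * f
    start = 0
    for k, size in enumerate(spec.cluster_sizes):
        cols = slice(start, start + size)
        mu[de_sets[k], cols] *= f * f * f
        labels_arr[cols] = f"type{k + 1}"
        start += size

    # NB(mean mu, size r): p = r / (r + mu)
    r = spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    gene_ids = [f"gene{i + 1:05d}" for i in range(spec.n_genes)]
    cell_ids = [f"cell{j + 1:05d}" for j in range(n_cells)]
    m = ExpressionMatrix(counts.astype(np.int64), gene_ids, cell_ids,
                         is_normalized=False)
    labels = {c: str(l) for c, l in zip(cell_ids, labels_arr)}
    if return_means:
        return m, labels, mu
    return m, labels


def write_labels(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tlabel\n")
        for c, lab in labels.items():
            fh.write(f"{c}\t{lab}\n")


def read_labels(path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            c, lab = line.rstrip("\n").split("\t")
            labels[c] = lab
    return labels
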