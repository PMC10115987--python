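"""Fano-space clustering of one tree node with automatic choice of k.

Small nodes (at most ``size_threshold`` cells, default 50) are clustered by
spectral clustering on a cosine similarity matrix, growing k from 1 until
the *similarity gain* — the best relative increase in intra-cluster
similarity brought by one more cluster — drops below the threshold ``ic``.
Large nodes are projected to 50 principal components and clustered with
k-means, with k chosen by the gap statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import cosine_similarity

from .features import FeatureSpace
from .io import ExpressionMatrix


@dataclass
class SimilarityMatrix:
    """Symmetric cosine similarity over a node's cells; diagonal 1."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.cell_ids):
            raise ValueError("similarity matrix shape does not match cell ids")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class KSelectionTrace:
    """Diagnostics of the progressive k search at one node."""

    method: str  # "spectral_gain" or "gap_statistic"
    records: list[dict] = field(default_factory=list)
    chosen_k: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def cosine_similarity_matrix(
    m_node: ExpressionMatrix, features: FeatureSpace
) -> SimilarityMatrix:
    """Pairwise cosine similarity of cells in the restricted gene space.

    All-zero cells are orthogonal to everything (similarity 0) but perfectly
    similar to themselves.  On nonnegative data cosine lands in [0, 1];
    negatives (possible for some normalizations) are clipped at 0 with a
    warning.
    """
    if len(features) == 0:
        raise ValueError("feature space is empty")
    sub = m_node.subset_genes(features.gene_ids)
    X = np.asarray(sub.values, dtype=float).T  # cells x genes
    S = cosine_similarity(X)
    if S.min() < -1e-12:
        warnings.warn("negative cosine similarities clipped to 0", stacklevel=2)
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, list(m_node.cell_ids))


def intra_cluster_similarity(S: SimilarityMatrix, labels: np.ndarray) -> np.ndarray:
    """Per-cell mean similarity over distinct pairs of its cluster.

    Every member of a cluster shares the cluster's value.  A singleton
    cluster is defined to have intra-cluster similarity 1 (perfectly
    homogeneous), which keeps the gain criterion from rewarding shattering.
    """
    labels = np.asarray(labels)
    out = np.empty(S.n, dtype=float)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        nc = idx.size
        if nc == 1:
            out[idx] = 1.0
            continue
        block = S.values[np.ix_(idx, idx)]
        total = block.sum() - np.trace(block)
        out[idx] = total / (nc * (nc - 1))
    return out


def similarity_gain(
    s_k: np.ndarray, s_k1: np.ndarray, labels_k1: np.ndarray
) -> float:
    """Gain of moving from a k-partition to a (k+1)-partition.

    Per new cluster m, ``r_m = sum_i (s_i^{k+1} - s_i^k) / sum_i s_i^k``
    over its members.  The gain is ``max_m r_m`` minus a term collecting
    the clusters whose similarity dropped, scaled by their size relative
    to the winning cluster: ``S = max_m r_m - sum_{m': r<0} (n_{m'}/n_m*)
    r_{m'}`` with m* the argmax cluster.

    Singleton clusters have no defined intra-cluster similarity (the
    within-pair average is 0/0), so they contribute no ``r`` term: a split
    is accepted only on the evidence of clusters whose homogeneity is
    measurable.  Any value could otherwise be assigned to a singleton, and
    an optimistic one would reward shattering noisy-but-pure groups.  When
    every new cluster is a singleton the gain is 0.
    """
    labels_k1 = np.asarray(labels_k1)
    r_list: list[float] = []
    size_list: list[int] = []
    for lab in np.unique(labels_k1):
        idx = labels_k1 == lab
        nc = int(idx.sum())
        if nc < 2:
            continue
        denom = s_k[idx].sum()
        if denom == 0:
            warnings.warn("zero intra-cluster similarity denominator; r set to 0",
                          stacklevel=2)
            r_list.append(0.0)
        else:
            r_list.append(float((s_k1[idx] - s_k[idx]).sum() / denom))
        size_list.append(nc)
    if not r_list:
        return 0.0
    r = np.array(r_list)
    sizes = np.array(size_list)
    best = int(np.argmax(r))
    gain = r[best]
    neg = r < 0
    if neg.any():
        gain -= float((sizes[neg] / sizes[best] * r[neg]).sum())
    return float(gain)


def _spectral_partition(S: SimilarityMatrix, k: int, seed: int) -> np.ndarray:
    """Spectral clustering on a precomputed similarity matrix.

    Symmetric normalized Laplacian, k smallest eigenvectors, rows normalized
    to unit length, k-means in the embedding.  k=1 needs no decomposition.
    """
    n = S.n
    if k <= 1 or n <= 1:
        return np.zeros(n, dtype=int)
    k = min(k, n)
    d = S.values.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(np.where(d > 0, d, 1.0))
    L = np.eye(n) - d_inv_sqrt[:, None] * S.values * d_inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    _, vecs = eigh(L, subset_by_index=[0, k - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    emb = vecs / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(emb)


def select_k_spectral(
    S: SimilarityMatrix,
    ic: float = 0.12,
    k_max: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, KSelectionTrace]:
    """Grow k from 1 until the similarity gain falls below ``ic``.

    Returns the last accepted partition.  k = 1 (a single cluster) is the
    result when even the first split gains less than ``ic``.
    """
    if S.n < 2:
        return np.zeros(S.n, dtype=int), KSelectionTrace("spectral_gain", chosen_k=1)
    trace = KSelectionTrace("spectral_gain")
    labels = np.zeros(S.n, dtype=int)
    s_cur = intra_cluster_similarity(S, labels)
    k = 1
    k_cap = min(k_max, S.n)
    while k < k_cap:
        labels_next = _spectral_partition(S, k + 1, seed)
        s_next = intra_cluster_similarity(S, labels_next)
        gain = similarity_gain(s_cur, s_next, labels_next)
        sizes = np.bincount(labels_next)
        trace.records.append(
            {"k": k, "k_next": k + 1, "gain": gain,
             "sizes_next": sizes[sizes > 0].tolist()}
        )
        if gain < ic:
            break
        labels, s_cur = labels_next, s_next
        k += 1
    trace.chosen_k = int(np.unique(labels).size)
    return labels, trace


# ---------------------------------------------------------------------------
# Gap statistic (k-means path)
# ---------------------------------------------------------------------------

def _within_dispersion(X: np.ndarray, k: int, seed: int) -> float:
    """k-means within-cluster sum of squared distances to centroids."""
    if k == 1:
        mu = X.mean(axis=0)
        return float(((X - mu) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(X)
    return float(km.inertia_)


def gap_statistic_k(
    embedded: np.ndarray,
    k_max: int = 10,
    n_refs: int = 10,
    seed: int = 0,
) -> int:
    """Choose k for k-means by the gap statistic.

    ``gap(k)`` compares log within-cluster dispersion on the data against
    uniform reference draws over the data's bounding box; the chosen k is
    the smallest with ``gap(k) >= gap(k+1) - s_{k+1}``, where s is the
    reference standard deviation inflated by sqrt(1 + 1/B).  Computed
    incrementally so the search stops as soon as the rule fires.
    """
    X = np.asarray(embedded, dtype=float)
    n = X.shape[0]
    if n < 2:
        return 1
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    refs = [rng.uniform(lo, hi, size=X.shape) for _ in range(n_refs)]

    k_cap = min(k_max, n)

    def gap_and_s(k: int) -> tuple[float, float]:
        log_w = np.log(max(_within_dispersion(X, k, seed), 1e-300))
        log_w_ref = np.array(
            [np.log(max(_within_dispersion(R, k, seed), 1e-300)) for R in refs]
        )
        gap = float(log_w_ref.mean() - log_w)
        s = float(log_w_ref.std() * np.sqrt(1.0 + 1.0 / n_refs))
        return gap, s

    gap_k, _ = gap_and_s(1)
    for k in range(1, k_cap):
        gap_k1, s_k1 = gap_and_s(k + 1)
        if gap_k >= gap_k1 - s_k1:
            return k
        gap_k = gap_k1
    return k_cap


def cluster_node(
    m_node: ExpressionMatrix,
    features: FeatureSpace,
    size_threshold: int = 50,
    pca_dims: int = 50,
    ic: float = 0.12,
    k_max: int = 10,
    n_refs: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, KSelectionTrace]:
    """Cluster one node, routing by size.

    More than ``size_threshold`` cells: log1p variance stabilization, PCA
    to ``pca_dims`` components (capped at cells-1 and gene count), gap
    statistic for k, k-means.  Otherwise: cosine similarity + spectral
    clustering with gain-based k selection.  Fewer than 2 cells: the
    trivial single cluster.
    """
    n = m_node.n_cells
    if n < 2:
        return np.zeros(n, dtype=int), KSelectionTrace("degenerate", chosen_k=1)
    if n > size_threshold:
        sub = m_node.subset_genes(features.gene_ids)
        # log1p tames the heavy right tail of counts so within-cluster
        # dispersion is comparable against the uniform gap references
        X = np.log1p(np.asarray(sub.values, dtype=float).T)
        n_comp = min(pca_dims, n - 1, X.shape[1])
        emb = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
        k = gap_statistic_k(emb, k_max=k_max, n_refs=n_refs, seed=seed)
        trace = KSelectionTrace("gap_statistic", chosen_k=k)
        if k == 1:
            return np.zeros(n, dtype=int), trace
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(emb)
        trace.records.append(
            {"k": k, "sizes": np.bincount(labels).tolist()}
        )
        return labels, trace
    S = cosine_similarity_matrix(m_node, features)
    return select_k_spectral(S, ic=ic, k_max=k_max, seed=seed)
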