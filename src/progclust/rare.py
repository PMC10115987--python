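"""Rare cell detection inside one abundant cluster.

Given the cells of one cluster, the detector (i) selects locally high-Gini
genes as the working subspace, (ii) sets aside cells whose total expression
on those genes is below a noise threshold — high-Gini genes are barely
expressed on abundant cells, so those cells stay abundant — (iii) partitions
the remaining cells with Affinity Propagation on cosine similarities, and
(iv) scores every AP subcluster by how outlying it is: the ratio of its
mean within-similarity I_m to its mean similarity O_m to the rest of the
cluster.  Subclusters with score above ``ros`` (singletons: O_m below
``os``) are flagged rare and shed to the next clustering round.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .abundant import SimilarityMatrix, cosine_similarity_matrix
from .features import FeatureSpace, select_local_high_gini
from .io import ExpressionMatrix


@dataclass
class RareSubcluster:
    cell_ids: list[str]
    i_m: float  # NaN for singletons
    o_m: float
    outlier_score: float  # NaN for singletons
    flagged_rare: bool = False

    @property
    def is_singleton(self) -> bool:
        return len(self.cell_ids) == 1


@dataclass
class RareCallResult:
    """Outcome of rare detection at one node.

    ``subclusters`` partition the cells that survived the noise filter;
    ``noise_cells`` are the cells set aside as abundant before AP ran.
    """

    subclusters: list[RareSubcluster] = field(default_factory=list)
    noise_cells: list[str] = field(default_factory=list)

    def flagged_cells(self) -> list[str]:
        return [c for sc in self.subclusters if sc.flagged_rare for c in sc.cell_ids]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subcluster": i,
                "size": len(sc.cell_ids),
                "I_m": sc.i_m,
                "O_m": sc.o_m,
                "outlier_score": sc.outlier_score,
                "flagged_rare": sc.flagged_rare,
            }
            for i, sc in enumerate(self.subclusters)
        ]
        return pd.DataFrame(
            rows,
            columns=["subcluster", "size", "I_m", "O_m", "outlier_score",
                     "flagged_rare"],
        )


def noise_filter(
    m_node: ExpressionMatrix,
    features: FeatureSpace,
    noise_threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the node's cells by total expression on the selected genes.

    Returns boolean masks ``(retained, abundant)`` over the node's cells.
    "Below the threshold" is strict: a cell whose total equals the threshold
    is retained.
    """
    if len(features) == 0:
        raise ValueError("feature space is empty")
    sub = m_node.subset_genes(features.gene_ids)
    totals = np.asarray(sub.values, dtype=float).sum(axis=0)
    abundant = totals < noise_threshold
    return ~abundant, abundant


def affinity_propagation(
    S: SimilarityMatrix,
    damping: float = 0.5,
    preference: float | str | None = None,
    max_iter: int = 200,
    convergence_window: int = 15,
    return_exemplars: bool = False,
):
    """Exemplar-based clustering by responsibility/availability messages.

    The responsibility r(i,k) measures how suited point k is to serve as the
    exemplar of i given competing candidates; the availability a(i,k) how
    appropriate it is for i to choose k given k's support from others.  Both
    are updated with damping until the exemplar set is stable for
    ``convergence_window`` iterations.  The preference (self-similarity)
    defaults to the *minimum* off-diagonal similarity, favouring few
    clusters — a homogeneous rare group then stays one subcluster instead
    of being shattered (the median convention, available as
    ``preference="median"``, tends to split even 5 identical cells).
    Deterministic: no tie-breaking noise is injected.

    Returns integer labels (exemplars assigned to themselves); with
    ``return_exemplars`` also the sorted exemplar indices.
    """
    n = S.n
    if n < 2:
        labels = np.zeros(n, dtype=int)
        return (labels, np.zeros(min(n, 1), dtype=int)) if return_exemplars else labels
    Sm = S.values.astype(float).copy()
    if preference is None or isinstance(preference, str):
        off = Sm[~np.eye(n, dtype=bool)]
        policy = "min" if preference is None else preference
        if policy == "min":
            preference = float(off.min())
        elif policy == "median":
            preference = float(np.median(off))
        else:
            raise ValueError(f"unknown preference policy {policy!r}")
    np.fill_diagonal(Sm, preference)

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    history = np.zeros((n, convergence_window), dtype=bool)
    converged = False

    for it in range(max_iter):
        # responsibilities: r(i,k) = s(i,k) - max_{k'!=k} (a(i,k') + s(i,k'))
        AS = A + Sm
        first = np.argmax(AS, axis=1)
        max1 = AS[idx, first]
        AS[idx, first] = -np.inf
        max2 = AS.max(axis=1)
        Rnew = Sm - max1[:, None]
        Rnew[idx, first] = Sm[idx, first] - max2
        R = damping * R + (1 - damping) * Rnew

        # availabilities: a(i,k) = min(0, r(k,k) + sum_{i'!=i,k} max(0, r(i',k)))
        Rp = np.maximum(R, 0)
        np.fill_diagonal(Rp, np.diag(R))
        col = Rp.sum(axis=0)
        Anew = np.minimum(0, col[None, :] - Rp)
        # self-availability: a(k,k) = sum_{i'!=k} max(0, r(i',k))
        np.fill_diagonal(Anew, col - np.diag(Rp))
        A = damping * A + (1 - damping) * Anew

        exemplars = (np.diag(A) + np.diag(R)) > 0
        history[:, it % convergence_window] = exemplars
        if it >= convergence_window:
            counts = history.sum(axis=1)
            stable = np.all((counts == convergence_window) | (counts == 0))
            if stable and exemplars.any():
                converged = True
                break

    if not converged:
        warnings.warn("affinity propagation did not converge", stacklevel=2)

    I = np.flatnonzero((np.diag(A) + np.diag(R)) > 0)
    if I.size == 0:
        # no exemplar emerged; everything one cluster
        labels = np.zeros(n, dtype=int)
        return (labels, np.array([0])) if return_exemplars else labels
    c = np.argmax(Sm[:, I], axis=1)
    c[I] = np.arange(I.size)
    # refine: within each cluster the exemplar maximizes total similarity
    for k in range(I.size):
        members = np.flatnonzero(c == k)
        j = np.argmax(Sm[np.ix_(members, members)].sum(axis=0))
        I[k] = members[j]
    c = np.argmax(Sm[:, I], axis=1)
    c[I] = np.arange(I.size)
    exemplar_of = I[c]
    exemplars, labels = np.unique(exemplar_of, return_inverse=True)
    labels = labels.astype(int)
    if return_exemplars:
        return labels, exemplars
    return labels


def outlier_scores(
    S_full: SimilarityMatrix,
    partition: np.ndarray,
    retained: np.ndarray,
    noise_cells: list[str] | None = None,
) -> RareCallResult:
    """Score each AP subcluster against the rest of the node.

    ``S_full`` covers *all* node cells (noise-filtered ones included, so a
    rare subcluster contrasts against the abundant background).  For
    subcluster m: I_m is the mean similarity over distinct within pairs
    (NaN for singletons), O_m the mean similarity of members to every node
    cell outside m, and the outlier score I_m / O_m.
    """
    retained = np.asarray(retained)
    if retained.dtype != bool:
        mask = np.zeros(S_full.n, dtype=bool)
        mask[retained] = True
        retained = mask
    ret_idx = np.flatnonzero(retained)
    partition = np.asarray(partition)
    if partition.size != ret_idx.size:
        raise ValueError("partition length does not match retained cells")
    result = RareCallResult(
        noise_cells=(noise_cells if noise_cells is not None
                     else [S_full.cell_ids[i] for i in np.flatnonzero(~retained)])
    )
    all_idx = np.arange(S_full.n)
    for lab in np.unique(partition):
        members = ret_idx[partition == lab]
        outside = np.setdiff1d(all_idx, members, assume_unique=True)
        nm = members.size
        if nm > 1:
            block = S_full.values[np.ix_(members, members)]
            i_m = float((block.sum() - np.trace(block)) / (nm * (nm - 1)))
        else:
            i_m = float("nan")
        if outside.size:
            o_m = float(S_full.values[np.ix_(members, outside)].mean())
        else:
            o_m = float("nan")
        if np.isnan(i_m):
            score = float("nan")
        elif o_m == 0:
            warnings.warn("O_m is 0; outlier score set to +inf", stacklevel=2)
            score = float("inf")
        else:
            score = i_m / o_m
        result.subclusters.append(
            RareSubcluster(
                cell_ids=[S_full.cell_ids[i] for i in members],
                i_m=i_m,
                o_m=o_m,
                outlier_score=score,
            )
        )
    return result


def flag_rare(result: RareCallResult, ros: float = 3.5, os: float = 0.5) -> RareCallResult:
    """Apply the rare thresholds.

    Multi-cell subclusters are rare when outlier score is strictly greater
    than ``ros``; singletons (whose I_m is undefined) when O_m is strictly
    below ``os``.
    """
    out = RareCallResult(noise_cells=list(result.noise_cells))
    for sc in result.subclusters:
        if sc.is_singleton:
            flagged = not np.isnan(sc.o_m) and sc.o_m < os
        else:
            flagged = sc.outlier_score > ros
        out.subclusters.append(replace(sc, flagged_rare=bool(flagged)))
    return out


def detect_rare(
    m_node: ExpressionMatrix,
    noise_threshold: float,
    ros: float = 3.5,
    os: float = 0.5,
    gini_span: float = 0.9,
    gini_p_cutoff: float = 1e-4,
    ap_damping: float = 0.5,
    ap_preference: float | str | None = None,
    ap_max_iter: int = 200,
    ap_convergence_window: int = 15,
) -> RareCallResult | None:
    """Full rare-detection pass over one node; None when skipped.

    Skipped when no locally high-Gini gene is found or fewer than 2 cells
    survive the noise filter.
    """
    if m_node.n_cells < 3:
        return None
    features = select_local_high_gini(
        m_node, span=gini_span, p_cutoff=gini_p_cutoff
    )
    if len(features) == 0:
        return None
    retained, _ = noise_filter(m_node, features, noise_threshold)
    if retained.sum() < 2:
        return None
    S_full = cosine_similarity_matrix(m_node, features)
    ret_idx = np.flatnonzero(retained)
    S_ret = SimilarityMatrix(
        S_full.values[np.ix_(ret_idx, ret_idx)],
        [S_full.cell_ids[i] for i in ret_idx],
    )
    partition = affinity_propagation(
        S_ret,
        damping=ap_damping,
        preference=ap_preference,
        max_iter=ap_max_iter,
        convergence_window=ap_convergence_window,
    )
    result = outlier_scores(S_full, partition, retained)
    return flag_rare(result, ros=ros, os=os)
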