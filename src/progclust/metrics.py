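"""Weighted clustering agreement metrics for unbalanced data.

Classical NMI and Purity let a 10-cell population vanish next to a
2000-cell one.  Here every cell is weighted by the reciprocal of its
reference class size, so each class contributes equally to the cluster
probabilities: P(C) = sum_{i in C} w_i / sum_i w_i.  The same weights enter
the joint, the marginals and the purity proportions, keeping the three
consistent.  A dedicated protocol scores rare-cluster detection by merging
all small predicted clusters containing target cells.
"""

from __future__ import annotations

from collections import Counter

import numpy as np


def _aligned(predicted: dict[str, str], reference: dict[str, str]):
    if set(predicted) != set(reference):
        raise ValueError("predicted and reference cover different cell sets")
    cells = list(predicted)
    return cells, [predicted[c] for c in cells], [reference[c] for c in cells]


def sample_weights(reference: dict[str, str]) -> dict[str, float]:
    """w_i = 1 / (size of cell i's reference class)."""
    sizes = Counter(reference.values())
    return {c: 1.0 / sizes[lab] for c, lab in reference.items()}


def _weighted_contingency(
    predicted: dict[str, str],
    reference: dict[str, str],
    weight_by: str = "reference",
) -> tuple[np.ndarray, list[str], list[str]]:
    """Weighted joint probability table (predicted x reference)."""
    cells, pred, ref = _aligned(predicted, reference)
    if weight_by == "reference":
        w = sample_weights(reference)
    elif weight_by == "predicted":
        w = sample_weights(predicted)
    else:
        raise ValueError("weight_by must be 'reference' or 'predicted'")
    pred_labels = sorted(set(pred))
    ref_labels = sorted(set(ref))
    pi = {lab: i for i, lab in enumerate(pred_labels)}
    ri = {lab: i for i, lab in enumerate(ref_labels)}
    table = np.zeros((len(pred_labels), len(ref_labels)))
    for c, p, r in zip(cells, pred, ref):
        table[pi[p], ri[r]] += w[c]
    table /= table.sum()
    return table, pred_labels, ref_labels


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def weighted_nmi(
    predicted: dict[str, str],
    reference: dict[str, str],
    weight_by: str = "reference",
) -> float:
    """Weighted normalized mutual information, 2 I(X,Y) / (H(X) + H(Y)).

    All probabilities come from the weighted contingency table.  Returns 1
    for identical partitions, 0 when either side carries no information
    (e.g. a single predicted cluster).
    """
    table, _, _ = _weighted_contingency(predicted, reference, weight_by)
    px = table.sum(axis=1)
    py = table.sum(axis=0)
    hx, hy = _entropy(px), _entropy(py)
    if hx + hy == 0:
        return 0.0
    outer = px[:, None] * py[None, :]
    mask = table > 0
    mi = float((table[mask] * np.log(table[mask] / outer[mask])).sum())
    return 2.0 * mi / (hx + hy)


def weighted_purity(
    predicted: dict[str, str],
    reference: dict[str, str],
    weight_by: str = "reference",
) -> float:
    """Weighted purity: sum_j P(C_j) max_class (weighted proportion in C_j).

    Ties in the within-cluster maximum resolve to the lexicographically
    first class, which does not change the value.
    """
    table, _, _ = _weighted_contingency(predicted, reference, weight_by)
    # row max = P(C_j) * max weighted class proportion within cluster j
    return float(table.max(axis=1).sum())


def rare_cluster_prf(
    predicted: dict[str, str],
    reference: dict[str, str],
    target_class: str,
    max_size: int = 20,
) -> tuple[float, float, float, int]:
    """Recall/precision/F1 for one rare reference class.

    Predicted clusters with fewer than ``max_size`` cells that contain at
    least one target cell are merged into one detected set, which is then
    scored against the reference target class.  Also returns how many
    clusters were merged.
    """
    cells, pred, ref = _aligned(predicted, reference)
    target_cells = {c for c, r in zip(cells, ref) if r == target_class}
    if not target_cells:
        raise ValueError(f"target class {target_class!r} absent from reference")
    sizes = Counter(pred)
    members: dict[str, list[str]] = {}
    for c, p in zip(cells, pred):
        members.setdefault(p, []).append(c)
    merged: set[str] = set()
    n_rare_clusters = 0
    for lab, cs in members.items():
        if sizes[lab] < max_size and any(c in target_cells for c in cs):
            merged.update(cs)
            n_rare_clusters += 1
    if not merged:
        return 0.0, 0.0, 0.0, 0
    tp = len(merged & target_cells)
    recall = tp / len(target_cells)
    precision = tp / len(merged)
    f1 = (0.0 if tp == 0
          else 2 * precision * recall / (precision + recall))
    return recall, precision, f1, n_rare_clusters
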