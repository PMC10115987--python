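"""Independent brute-force oracles: naive nested-loop implementations used
only to check the package's vectorized ones."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def fano_oracle(g) -> float:
    g = list(map(float, g))
    n = len(g)
    mu = sum(g) / n
    if mu == 0:
        return float("nan")
    var = sum((x - mu) ** 2 for x in g) / n
    return var / mu


def gini_mad_oracle(g) -> float:
    """Gini via the mean-absolute-difference identity
    sum_ij |x_i - x_j| / (2 n^2 mean)."""
    g = list(map(float, g))
    n = len(g)
    mu = sum(g) / n
    if mu == 0:
        return float("nan")
    mad = sum(abs(a - b) for a in g for b in g)
    return mad / (2 * n * n * mu)


def intra_similarity_oracle(S: np.ndarray, labels) -> np.ndarray:
    labels = list(labels)
    n = len(labels)
    out = np.empty(n)
    for i in range(n):
        members = [j for j in range(n) if labels[j] == labels[i]]
        if len(members) == 1:
            out[i] = 1.0
            continue
        total = 0.0
        for a in members:
            for b in members:
                if a != b:
                    total += S[a, b]
        out[i] = total / (len(members) * (len(members) - 1))
    return out


def gain_oracle(s_k, s_k1, labels_k1) -> float:
    """Nested-loop similarity gain; singletons carry no r term."""
    labels_k1 = list(labels_k1)
    rs, sizes = [], []
    for lab in sorted(set(labels_k1), key=str):
        members = [i for i, l in enumerate(labels_k1) if l == lab]
        if len(members) < 2:
            continue
        denom = sum(s_k[i] for i in members)
        num = sum(s_k1[i] - s_k[i] for i in members)
        rs.append(0.0 if denom == 0 else num / denom)
        sizes.append(len(members))
    if not rs:
        return 0.0
    best = max(range(len(rs)), key=lambda j: rs[j])
    gain = rs[best]
    for j, r in enumerate(rs):
        if r < 0:
            gain -= sizes[j] / sizes[best] * r
    return gain


def weighted_contingency_oracle(predicted: dict, reference: dict):
    """Joint weighted probability table as plain dicts."""
    class_sizes = Counter(reference.values())
    w = {c: 1.0 / class_sizes[reference[c]] for c in reference}
    total = sum(w.values())
    joint: dict[tuple, float] = {}
    for c in predicted:
        key = (predicted[c], reference[c])
        joint[key] = joint.get(key, 0.0) + w[c] / total
    return joint


def weighted_nmi_oracle(predicted: dict, reference: dict) -> float:
    joint = weighted_contingency_oracle(predicted, reference)
    px: dict = {}
    py: dict = {}
    for (x, y), p in joint.items():
        px[x] = px.get(x, 0.0) + p
        py[y] = py.get(y, 0.0) + p
    hx = -sum(p * math.log(p) for p in px.values() if p > 0)
    hy = -sum(p * math.log(p) for p in py.values() if p > 0)
    if hx + hy == 0:
        return 0.0
    mi = sum(
        p * math.log(p / (px[x] * py[y]))
        for (x, y), p in joint.items()
        if p > 0
    )
    return 2 * mi / (hx + hy)


def weighted_purity_oracle(predicted: dict, reference: dict) -> float:
    joint = weighted_contingency_oracle(predicted, reference)
    best: dict = {}
    for (x, _y), p in joint.items():
        best[x] = max(best.get(x, 0.0), p)
    # row max of the joint = P(C_j) * max weighted class share
    out = 0.0
    for x in best:
        row = [p for (xx, _), p in joint.items() if xx == x]
        out += max(row)
    return out
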