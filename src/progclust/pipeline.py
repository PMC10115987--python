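"""Progressive clustering: grow the round-1 tree, pool shed rare cells,
grow the round-2 tree, emit the final assignment.

Round 1 divisively clusters all cells in the Fano feature space; after each
split, every child runs Gini-based rare detection and sheds its flagged
cells.  Round 2 pools every shed cell and grows a second tree with the same
machinery — rare pools are small, so the spectral path dominates there.
The final flat clustering is the union of the leaves of both trees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

from . import abundant, rare
from .features import FeatureSpace, select_top_fano
from .io import Assignment, AssignmentRecord, ExpressionMatrix


@dataclass
class ProgClustConfig:
    """Every tunable of the pipeline, with its default.

    ``noise_threshold`` defaults to 30 on raw counts and 1 on normalized
    input; leave it None to get that behavior, or set it explicitly.
    """

    top_k_fano: int = 1000
    size_threshold: int = 50
    pca_dims: int = 50
    ic: float = 0.12
    noise_threshold: float | None = None
    ros: float = 3.5
    os: float = 0.5
    max_depth: int = 2
    k_max: int = 10
    n_refs: int = 10
    gini_span: float = 0.9
    gini_p_cutoff: float = 1e-4
    ap_damping: float = 0.5
    ap_preference: float | str | None = None
    ap_max_iter: int = 200
    ap_convergence_window: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be at least 1")
        for name in ("top_k_fano", "size_threshold", "ic", "ros", "os", "k_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def resolve_noise_threshold(self, is_normalized: bool) -> float:
        if self.noise_threshold is not None:
            return self.noise_threshold
        return 1.0 if is_normalized else 30.0


@dataclass
class ClusterNode:
    """One node of a progressive clustering tree."""

    cell_ids: list[str]
    depth: int
    node_path: list[int] = field(default_factory=list)
    features: FeatureSpace | None = None
    children: list["ClusterNode"] = field(default_factory=list)
    rare_shed: list[str] = field(default_factory=list)
    rare_call: rare.RareCallResult | None = None
    trace: abundant.KSelectionTrace | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["ClusterNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def all_shed(self) -> list[str]:
        shed = list(self.rare_shed)
        for child in self.children:
            shed.extend(child.all_shed())
        return shed

    def to_dict(self) -> dict:
        return {
            "node_path": self.node_path,
            "depth": self.depth,
            "n_cells": len(self.cell_ids),
            "n_rare_shed": len(self.rare_shed),
            "features": None if self.features is None else len(self.features),
            "children": [c.to_dict() for c in self.children],
        }


def _node_seed(master_seed: int, round_no: int, node_path: list[int]) -> int:
    """Deterministic per-node seed; unrelated nodes never share streams."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(round_no, *node_path))
    return int(ss.generate_state(1)[0] % (2**31))


def grow_tree(
    m: ExpressionMatrix,
    cell_ids: list[str],
    cfg: ProgClustConfig,
    round_no: int = 1,
    shed_as_leaves: bool = False,
) -> ClusterNode:
    """Grow one clustering tree over ``cell_ids``.

    At each node: Fano feature selection (merged with the parent's genes),
    size-routed clustering, one child per cluster; children at depth >= 1
    run rare detection first and shed flagged cells.  Recursion stops at
    ``cfg.max_depth`` or when k-selection keeps a single cluster.  With
    ``shed_as_leaves`` (the final round) each flagged AP subcluster becomes
    its own leaf instead of being pooled for a later round.
    """
    pos = {c: i for i, c in enumerate(m.cell_ids)}
    root = ClusterNode(cell_ids=list(cell_ids), depth=0)
    _grow(m, pos, root, None, cfg, round_no, shed_as_leaves)
    return root


def _subset(m: ExpressionMatrix, pos: dict[str, int], cells: list[str]) -> ExpressionMatrix:
    return m.subset_cells(np.array([pos[c] for c in cells], dtype=int))


def _grow(
    m: ExpressionMatrix,
    pos: dict[str, int],
    node: ClusterNode,
    parent_features: FeatureSpace | None,
    cfg: ProgClustConfig,
    round_no: int,
    shed_as_leaves: bool,
) -> None:
    # rare detection first (never at a tree's root)
    if node.depth >= 1:
        m_node = _subset(m, pos, node.cell_ids)
        noise_thr = cfg.resolve_noise_threshold(m.is_normalized)
        if math.isfinite(noise_thr):
            call = rare.detect_rare(
                m_node,
                noise_threshold=noise_thr,
                ros=cfg.ros,
                os=cfg.os,
                gini_span=cfg.gini_span,
                gini_p_cutoff=cfg.gini_p_cutoff,
                ap_damping=cfg.ap_damping,
                ap_preference=cfg.ap_preference,
                ap_max_iter=cfg.ap_max_iter,
                ap_convergence_window=cfg.ap_convergence_window,
            )
            node.rare_call = call
            if call is not None:
                flagged_sets = [
                    sc.cell_ids for sc in call.subclusters if sc.flagged_rare
                ]
                flagged = [c for cs in flagged_sets for c in cs]
                if flagged and shed_as_leaves:
                    # final round: flagged subclusters become rare leaves
                    keep = [c for c in node.cell_ids if c not in set(flagged)]
                    if keep:
                        node.rare_shed = []
                        kept_child = ClusterNode(
                            cell_ids=keep,
                            depth=node.depth + 1,
                            node_path=node.node_path + [0],
                        )
                        node.children = [kept_child]
                        for j, cs in enumerate(flagged_sets, start=1):
                            node.children.append(
                                ClusterNode(
                                    cell_ids=list(cs),
                                    depth=node.depth + 1,
                                    node_path=node.node_path + [j],
                                )
                            )
                        _grow(m, pos, kept_child, parent_features, cfg,
                              round_no, shed_as_leaves)
                        return
                    # every cell flagged: node itself is the rare leaf
                    return
                if flagged:
                    node.rare_shed = flagged
                    node.cell_ids = [
                        c for c in node.cell_ids if c not in set(flagged)
                    ]

    if node.depth >= cfg.max_depth or len(node.cell_ids) < 2:
        return

    m_node = _subset(m, pos, node.cell_ids)
    try:
        features = select_top_fano(m_node, k=cfg.top_k_fano,
                                   parent_genes=parent_features)
    except ValueError:
        return  # all-zero node: leaf
    node.features = features
    seed = _node_seed(cfg.seed, round_no, node.node_path)
    labels, trace = abundant.cluster_node(
        m_node,
        features,
        size_threshold=cfg.size_threshold,
        pca_dims=cfg.pca_dims,
        ic=cfg.ic,
        k_max=cfg.k_max,
        n_refs=cfg.n_refs,
        seed=seed,
    )
    node.trace = trace
    uniq = np.unique(labels)
    if uniq.size <= 1:
        return  # k = 1: stop refining here
    for j, lab in enumerate(uniq):
        child_cells = [c for c, l in zip(node.cell_ids, labels) if l == lab]
        child = ClusterNode(
            cell_ids=child_cells,
            depth=node.depth + 1,
            node_path=node.node_path + [j],
        )
        node.children.append(child)
    for child in node.children:
        _grow(m, pos, child, features, cfg, round_no, shed_as_leaves)


def run_progclust(
    m: ExpressionMatrix, cfg: ProgClustConfig | None = None
) -> tuple[Assignment, ClusterNode, ClusterNode | None]:
    """Run the full two-round pipeline and return the flat assignment.

    Round 1 clusters all cells and sheds rare candidates; round 2 pools the
    shed cells and clusters them with the same machinery (flagged
    subclusters there become rare leaves directly).  Final labels are the
    leaves of both trees: ``r1_<path>`` abundant, ``r2_<path>`` rare.
    """
    if cfg is None:
        cfg = ProgClustConfig()
    tree1 = grow_tree(m, list(m.cell_ids), cfg, round_no=1)
    pooled = tree1.all_shed()

    assignment = Assignment()
    for leaf in tree1.leaves():
        label = "r1_" + "/".join(str(i) for i in leaf.node_path)
        for c in leaf.cell_ids:
            assignment.records[c] = AssignmentRecord(
                label=label, round=1, node_path=list(leaf.node_path), is_rare=False
            )

    tree2: ClusterNode | None = None
    if len(pooled) >= 2:
        tree2 = grow_tree(m, pooled, cfg, round_no=2, shed_as_leaves=True)
        for leaf in tree2.leaves():
            label = "r2_" + "/".join(str(i) for i in leaf.node_path)
            for c in leaf.cell_ids:
                assignment.records[c] = AssignmentRecord(
                    label=label, round=2, node_path=list(leaf.node_path),
                    is_rare=True,
                )
    elif pooled:
        for c in pooled:
            assignment.records[c] = AssignmentRecord(
                label="r2_", round=2, node_path=[], is_rare=True
            )

    # deterministic row order: input cell order
    ordered = Assignment(
        {c: assignment.records[c] for c in m.cell_ids if c in assignment.records}
    )
    if len(ordered) != m.n_cells:
        missing = set(m.cell_ids) - set(ordered.records)
        raise RuntimeError(f"cells lost by the pipeline: {sorted(missing)[:5]}")
    return ordered, tree1, tree2


def display_labels(assignment: Assignment) -> dict[str, str]:
    """Map canonical leaf labels to c1..cK by descending cluster size."""
    sizes: dict[str, int] = {}
    for rec in assignment.records.values():
        sizes[rec.label] = sizes.get(rec.label, 0) + 1
    ranked = sorted(sizes, key=lambda lab: (-sizes[lab], lab))
    return {lab: f"c{i + 1}" for i, lab in enumerate(ranked)}


def tree_to_json(tree: ClusterNode, path) -> None:
    with open(path, "w") as fh:
        json.dump(tree.to_dict(), fh, indent=2)


def config_to_dict(cfg: ProgClustConfig) -> dict:
    return asdict(cfg)
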