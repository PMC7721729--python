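"""Cross-resolution phenotype dendrogram.

Clusterings at successive stable values of K are linked into a tree: each
cluster at the finer level attaches to the coarser-level cluster with which
it shares the largest Jaccard index of patient sets, with branch length
(dissimilarity) 1 - J.  The root aggregates the whole cohort and its
children are the clusters at the smallest stable K.  Branch points (nodes
acquiring two or more children) mark the K at which a coarse patient group
splits into finer phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusteringResult

logger = logging.getLogger(__name__)


def pairwise_cluster_jaccard(labels_A: np.ndarray, labels_B: np.ndarray) -> np.ndarray:
    """K_A x K_B matrix of Jaccard indices between two partitions' clusters.

    Entry (i, j) = |A_i ∩ B_j| / |A_i ∪ B_j|.  Both partitions must be
    defined on the same patients, in the same order.
    """
    labels_A = np.asarray(labels_A)
    labels_B = np.asarray(labels_B)
    if labels_A.shape != labels_B.shape:
        raise ValueError("partitions are defined on different patient sets")
    ka = int(labels_A.max()) + 1
    kb = int(labels_B.max()) + 1
    contingency = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(contingency, (labels_A, labels_B), 1)
    sizes_a = contingency.sum(axis=1)
    sizes_b = contingency.sum(axis=0)
    union = sizes_a[:, None] + sizes_b[None, :] - contingency
    return np.where(union > 0, contingency / union, 0.0)


@dataclass
class ClusterNode:
    """One cluster at one resolution level of the dendrogram."""

    K: int
    cluster_id: int
    patient_ids: frozenset[str]
    parent: Optional["ClusterNode"] = None
    link_dissimilarity: float = 0.0
    children: list["ClusterNode"] = field(default_factory=list)

    @property
    def name(self) -> str:
        return "root" if self.parent is None and self.K == 0 else f"K{self.K}_C{self.cluster_id}"

    def __repr__(self) -> str:  # patient sets are large; keep repr terse
        return f"ClusterNode({self.name}, n={len(self.patient_ids)}, d={self.link_dissimilarity:.3g})"


@dataclass
class PhenotypeDendrogram:
    """Tree of clusters across stable K values, edges weighted by 1 - J."""

    root: ClusterNode
    levels: tuple[int, ...]
    nodes: dict[tuple[int, int], ClusterNode]

    @property
    def split_points(self) -> dict[str, int]:
        """Node name -> K at which the node splits into >= 2 children."""
        out = {}
        for node in [self.root, *self.nodes.values()]:
            if len(node.children) >= 2:
                out[node.name] = node.children[0].K
        return out

    def level_nodes(self, K: int) -> list[ClusterNode]:
        return [self.nodes[(K, c)] for c in sorted(c for (k, c) in self.nodes if k == K)]

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for (K, cid) in sorted(self.nodes):
            node = self.nodes[(K, cid)]
            parent = node.parent
            rows.append(
                (
                    K,
                    cid,
                    parent.K,
                    parent.cluster_id,
                    1.0 - node.link_dissimilarity,
                    node.link_dissimilarity,
                )
            )
        return pd.DataFrame(
            rows,
            columns=["child_K", "child_id", "parent_K", "parent_id", "jaccard", "dissimilarity"],
        )


def build_dendrogram(
    clusterings: Mapping[int, ClusteringResult], patient_index: Sequence[str]
) -> PhenotypeDendrogram:
    """Link clusters at consecutive stable K levels by maximum Jaccard.

    Each cluster at level K_{m+1} attaches to the level-K_m cluster with the
    largest Jaccard overlap of patient sets (ties broken toward the lower
    cluster_id and logged); its branch length is 1 minus that maximum.
    """
    if not clusterings:
        raise ValueError("clusterings map is empty")
    levels = tuple(sorted(clusterings))
    n = len(patient_index)
    for K, res in clusterings.items():
        if len(res.labels) != n:
            raise ValueError(f"clustering at K={K} is not defined on the given patients")
    pid = np.asarray(patient_index, dtype=object)
    root = ClusterNode(K=0, cluster_id=0, patient_ids=frozenset(patient_index))
    nodes: dict[tuple[int, int], ClusterNode] = {}

    first = levels[0]
    for cid in range(clusterings[first].K):
        members = frozenset(pid[clusterings[first].labels == cid])
        node = ClusterNode(
            K=first,
            cluster_id=cid,
            patient_ids=members,
            parent=root,
            link_dissimilarity=1.0 - len(members) / n,
        )
        root.children.append(node)
        nodes[(first, cid)] = node

    for coarse_K, fine_K in zip(levels, levels[1:]):
        jac = pairwise_cluster_jaccard(
            clusterings[coarse_K].labels, clusterings[fine_K].labels
        )
        for cid in range(clusterings[fine_K].K):
            col = jac[:, cid]
            parent_id = int(col.argmax())
            best = float(col[parent_id])
            ties = np.flatnonzero(col == best)
            if len(ties) > 1:
                logger.info(
                    "ambiguous parent for K%d_C%d (candidates %s); keeping C%d",
                    fine_K, cid, ties.tolist(), parent_id,
                )
            members = frozenset(pid[clusterings[fine_K].labels == cid])
            node = ClusterNode(
                K=fine_K,
                cluster_id=cid,
                patient_ids=members,
                parent=nodes[(coarse_K, parent_id)],
                link_dissimilarity=1.0 - best,
            )
            nodes[(coarse_K, parent_id)].children.append(node)
            nodes[(fine_K, cid)] = node

    return PhenotypeDendrogram(root=root, levels=levels, nodes=nodes)


def _newick_name(node: ClusterNode, labels: Mapping[str, str] | None) -> str:
    name = node.name
    return labels.get(name, name) if labels else name


def _newick(node: ClusterNode, labels: Mapping[str, str] | None) -> str:
    if not node.children:
        return f"{_newick_name(node, labels)}:{node.link_dissimilarity:g}"
    inner = ",".join(_newick(c, labels) for c in node.children)
    if node.parent is None:
        # the root carries a name only when the caller supplies one
        name = labels.get("root", "") if labels else ""
        return f"({inner}){name}"
    return f"({inner}){_newick_name(node, labels)}:{node.link_dissimilarity:g}"


def to_newick(tree: PhenotypeDendrogram, labels: Mapping[str, str] | None = None) -> str:
    """Newick serialization; branch lengths are the link dissimilarities.

    Node names default to ``K{K}_C{cluster_id}`` (root is ``root``) and can
    be overridden via ``labels``.
    """
    return _newick(tree.root, labels) + ";"
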