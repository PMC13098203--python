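"""Cohort comparison: reaction presence/absence, distances, clustering.

Strain models carved from one universal share a reaction namespace, so
their content differences reduce to a boolean strain x reaction matrix.
Distances over that matrix (Jaccard by default) feed average-linkage
hierarchical clustering; with a clean species split the k=2 cut recovers
the species labels.  Restored-but-disconnected reactions count as present:
they carry genomic evidence even without network context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from cobra import Model
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .pan_curation import PanModel

__all__ = [
    "presence_matrix",
    "distance",
    "Dendrogram",
    "hcluster",
    "pathway_completeness",
]


def presence_matrix(pan: PanModel) -> pd.DataFrame:
    """Strain x reaction boolean matrix over the pan-model reaction set,
    with strains in sorted order for determinism."""
    return pan.presence.sort_index().copy()


def distance(matrix: pd.DataFrame, metric: str = "jaccard") -> pd.DataFrame:
    """Pairwise strain distance from reaction presence/absence."""
    if metric not in ("jaccard", "hamming"):
        raise ValueError(f"unsupported metric {metric!r}")
    if matrix.shape[0] < 2:
        raise ValueError("need at least two strains")
    matrix = matrix.sort_index()
    condensed = pdist(matrix.values.astype(bool), metric=metric)
    dense = squareform(condensed)
    return pd.DataFrame(dense, index=matrix.index, columns=matrix.index)


@dataclass
class Dendrogram:
    """Merge tree over strains with heights and a cut-to-k accessor."""

    linkage_matrix: np.ndarray
    labels: List[str]

    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> List[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> Dict[str, int]:
        """Cluster assignment (1..k) per strain at a k-cluster cut."""
        assignment = hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            ld = max(node.dist - node.left.dist, 0.0)
            rd = max(node.dist - node.right.dist, 0.0)
            return f"({left}:{ld:.6g},{right}:{rd:.6g})"

        return walk(tree) + ";"


def hcluster(dist: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Deterministic hierarchical clustering of a strain distance matrix.

    Strains are processed in id order, so permuting the input leaves the
    cut labels invariant.
    """
    if linkage not in ("average", "complete", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    dist = dist.sort_index().loc[:, sorted(dist.columns)]
    if list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix index and columns differ")
    condensed = squareform(dist.values, checks=True)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(Z, list(dist.index))


def pathway_completeness(model: Model, reaction_ids: Sequence[str]
                         ) -> Tuple[List[str], List[str], bool]:
    """Membership test for a reaction list (a pathway definition)."""
    present = [rid for rid in reaction_ids if rid in model.reactions]
    missing = [rid for rid in reaction_ids if rid not in model.reactions]
    return present, missing, not missing
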