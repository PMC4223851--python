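"""Hierarchical expression clustering with a fractional tree cut.

Genes are clustered by Euclidean distance over the six TMM-normalized stage
FPKM values (distances on raw FPKM; displayed profiles use log2
median-centering) with complete-linkage agglomeration, and subclusters are
the connected components below ``fraction * max merge height``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


@dataclass
class LinkageTree:
    merges: np.ndarray       # scipy linkage matrix (n-1 x 4)
    leaf_ids: list

    @property
    def max_height(self) -> float:
        return float(self.merges[:, 2].max()) if len(self.merges) else 0.0


def expression_distance(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Euclidean dissimilarity matrix over stage expression."""
    m = pd.DataFrame(fpkm).astype(float)
    if m.isna().any().any():
        raise ValueError("missing values in expression matrix")
    d = squareform(pdist(m.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=m.index, columns=m.index)


def complete_linkage(dissimilarity: pd.DataFrame) -> LinkageTree:
    """Complete-linkage agglomeration of a precomputed dissimilarity matrix."""
    d = pd.DataFrame(dissimilarity)
    if d.shape[0] < 2:
        raise ValueError("clustering needs at least two items")
    condensed = squareform(d.to_numpy(), checks=False)
    merges = hierarchy.linkage(condensed, method="complete")
    return LinkageTree(merges=merges, leaf_ids=list(d.index))


def cut_at_fraction(tree: LinkageTree, fraction: float = 0.45) -> pd.Series:
    """Subcluster labels from cutting at ``fraction`` of the maximum height."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    height = fraction * tree.max_height
    flat = hierarchy.fcluster(tree.merges, t=height, criterion="distance")
    return pd.Series(flat, index=tree.leaf_ids, name="subcluster")


def subcluster_profiles(fpkm: pd.DataFrame, assignment: pd.Series,
                        pseudocount: float = 1.0) -> dict[int, pd.DataFrame]:
    """Per-subcluster matrices of log2(FPKM + pseudocount), median-centered per gene."""
    log_expr = np.log2(pd.DataFrame(fpkm).astype(float).clip(lower=0.0) + pseudocount)
    centered = log_expr.sub(log_expr.median(axis=1), axis=0)
    return {int(label): centered.loc[assignment.index[assignment == label]]
            for label in sorted(assignment.unique())}


def cluster_expression(fpkm: pd.DataFrame, fraction: float = 0.45):
    """Distance -> complete linkage -> fractional cut; returns (tree, labels, profiles)."""
    tree = complete_linkage(expression_distance(fpkm))
    labels = cut_at_fraction(tree, fraction)
    return tree, labels, subcluster_profiles(fpkm, labels)


def cophenetic_matrix(tree: LinkageTree) -> pd.DataFrame:
    d = squareform(hierarchy.cophenet(tree.merges))
    return pd.DataFrame(d, index=tree.leaf_ids, columns=tree.leaf_ids)
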