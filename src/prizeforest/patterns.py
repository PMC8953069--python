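"""Cross-treatment logFC pattern analysis.

Works on a "logFC panel": one row per gene, one log2-fold-change column per
treatment (e.g. ALPHA, SALPHA, SBETA, SOR), with missing values where a gene
was not tested under a treatment.  Provides pairwise Pearson correlation of
treatments, ranking of the most commonly perturbed genes by the sum of
absolute logFC, and Euclidean hierarchical clustering of logFC profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import InputError

__all__ = [
    "pairwise_pearson",
    "top_k_by_abs_logfc",
    "hier_cluster",
    "HierResult",
]


def pairwise_pearson(panel: pd.DataFrame, min_overlap: int = 3) -> pd.DataFrame:
    """Treatment x treatment Pearson correlations over pairwise-complete genes.

    Pairs with fewer than ``min_overlap`` jointly observed genes are NaN
    (undefined), never silently zero.  The diagonal is 1 and the matrix is
    symmetric.
    """
    if panel.shape[1] < 2:
        raise InputError("need at least two treatments for correlation")
    corr = panel.corr(method="pearson", min_periods=min_overlap)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def top_k_by_abs_logfc(panel: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """The k genes with the largest sum of |logFC| across treatments.

    Missing values count as 0; ties break lexicographically by gene id.
    Returns a DataFrame (gene order = rank order) with a ``score`` column.
    """
    if k > len(panel):
        raise InputError(f"k={k} exceeds the number of genes ({len(panel)})")
    score = panel.abs().fillna(0.0).sum(axis=1)
    order = pd.DataFrame(
        {"_score": score, "_gene": [str(i) for i in panel.index]}, index=panel.index
    ).sort_values(["_score", "_gene"], ascending=[False, True])
    top = panel.loc[order.index[:k]].copy()
    top["score"] = order["_score"].iloc[:k]
    return top


class HierResult:
    """Agglomerative clustering result: linkage matrix, leaf order, Newick tree."""

    def __init__(self, linkage: np.ndarray, labels: list[str]):
        self.linkage = linkage
        self.labels = list(labels)
        self.leaf_order = [
            self.labels[i] for i in hierarchy.leaves_list(linkage)
        ] if len(labels) > 1 else list(labels)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        if len(self.labels) == 1:
            return f"{self.labels[0]};"
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left = rec(node.left)
            right = rec(node.right)
            bl = node.dist - node.left.dist
            br = node.dist - node.right.dist
            return f"({left}:{bl:.10g},{right}:{br:.10g})"

        return rec(tree) + ";"


def hier_cluster(matrix, method: str = "complete") -> HierResult:
    """Hierarchical clustering with Euclidean distance (complete linkage default).

    ``matrix`` is a DataFrame (rows clustered, e.g. genes x treatments) or
    array.  Rows with missing values raise an error instructing the caller to
    impute or drop them first.  scipy's linkage is deterministic: equal
    distances merge lower-index clusters first.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(i) for i in matrix.index]
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(len(x))]
    if np.isnan(x).any():
        raise InputError(
            "matrix contains missing values; drop or impute incomplete rows before clustering"
        )
    if len(x) < 2:
        return HierResult(np.empty((0, 4)), labels)
    z = hierarchy.linkage(pdist(x, metric="euclidean"), method=method)
    return HierResult(z, labels)
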