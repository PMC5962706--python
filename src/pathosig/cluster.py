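"""Hierarchical clustering of samples and Calinski-Harabasz model selection.

Samples are clustered on their organism-aggregated signature profiles
using Euclidean distance and complete linkage, without standardizing the
input.  The number of clusters is chosen by maximizing the
Calinski-Harabasz (CH) index

    CH(k) = [B / (k - 1)] / [W / (n - k)]

where B is the between-cluster and W the within-cluster sum of squared
Euclidean deviations.  Cluster-vs-cluster signature contrasts use Welch
t-tests (two-sided by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from pathosig.detect import welch_t_test

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """Linkage, per-k labels, CH curve and the selected cluster count."""

    linkage: np.ndarray                 # scipy linkage matrix, (n-1) x 4
    sample_ids: list[str]
    labels: dict[int, np.ndarray]       # k -> integer labels, 0..k-1
    ch_curve: dict[int, float]
    selected_k: int

    @property
    def selected_labels(self) -> np.ndarray:
        return self.labels[self.selected_k]

    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in hierarchy.leaves_list(self.linkage)]


def _as_matrix(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        ids = [str(s) for s in matrix.index]
    else:
        values = np.asarray(matrix, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        ids = [str(i) for i in range(values.shape[0])]
    return values, ids


def hierarchical_cluster(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Complete-linkage agglomeration on Euclidean distances (unscaled input)."""
    values, ids = _as_matrix(matrix)
    if values.shape[0] < 2:
        raise ValueError("clustering needs at least 2 samples")
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"missing value at sample {ids[i]!r}, column {j}")
    return hierarchy.linkage(values, method="complete", metric="euclidean")


def cut_tree(linkage: np.ndarray, k: int) -> np.ndarray:
    """Labels (0..k-1) from cutting the dendrogram into exactly k groups."""
    n = linkage.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    labels = hierarchy.cut_tree(linkage, n_clusters=k).ravel()
    if len(np.unique(labels)) != k:
        raise ValueError(f"cut produced {len(np.unique(labels))} groups instead of {k}")
    return labels


def calinski_harabasz(matrix: pd.DataFrame | np.ndarray, labels: Sequence[int]) -> float:
    """CH index from its definition by direct summation.

    Returns +inf (with a warning) when the within-cluster scatter W is
    exactly zero, e.g. clusters of identical points.
    """
    values, _ = _as_matrix(matrix)
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("labels and matrix rows differ in length")
    uniq = np.unique(labels)
    n, k = values.shape[0], uniq.size
    if not 2 <= k <= n - 1:
        raise ValueError(f"number of clusters must be in [2, {n - 1}], got {k}")
    overall = values.mean(axis=0)
    between = 0.0
    within = 0.0
    for lab in uniq:
        cluster = values[labels == lab]
        centroid = cluster.mean(axis=0)
        between += cluster.shape[0] * float(np.sum((centroid - overall) ** 2))
        within += float(np.sum((cluster - centroid) ** 2))
    if within == 0.0:
        logger.warning("zero within-cluster scatter; CH index is infinite")
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


def select_cluster_count(
    matrix: pd.DataFrame | np.ndarray,
    k_range: Sequence[int] | None = None,
) -> tuple[int, dict[int, float], np.ndarray]:
    """Choose the cluster count maximizing the CH index over complete-linkage cuts.

    Default k range is 2..min(10, n-1).  Ties resolve to the smallest k.
    Returns ``(selected_k, ch_curve, linkage)``.
    """
    values, _ = _as_matrix(matrix)
    n = values.shape[0]
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    k_list = sorted(set(int(k) for k in k_range))
    if not k_list:
        raise ValueError("k_range is empty")
    if k_list[0] < 2 or k_list[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    linkage = hierarchical_cluster(values)
    curve = {k: calinski_harabasz(values, cut_tree(linkage, k)) for k in k_list}
    best_k = k_list[0]
    for k in k_list[1:]:
        if curve[k] > curve[best_k]:
            best_k = k
    return best_k, curve, linkage


def cluster_samples(
    matrix: pd.DataFrame, k_range: Sequence[int] | None = None
) -> ClusterResult:
    """Full clustering of a samples x organisms matrix with CH selection."""
    selected_k, curve, linkage = select_cluster_count(matrix, k_range)
    labels = {k: cut_tree(linkage, k) for k in curve}
    return ClusterResult(
        linkage=linkage,
        sample_ids=[str(s) for s in matrix.index],
        labels=labels,
        ch_curve=curve,
        selected_k=selected_k,
    )


def cluster_contrast(
    matrix: pd.DataFrame,
    ids_a: Sequence[str],
    ids_b: Sequence[str],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-organism Welch t contrast between two sample clusters.

    logFC = mean(cluster a) - mean(cluster b) of the aggregated signature
    signal, log2 units.  Swapping the clusters negates t and logFC.
    """
    ids_a, ids_b = list(ids_a), list(ids_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each cluster needs at least 2 samples for a contrast")
    a = matrix.loc[ids_a].to_numpy().T  # organisms x samples
    b = matrix.loc[ids_b].to_numpy().T
    t, p = welch_t_test(a, b, alternative=alternative)
    return pd.DataFrame(
        {
            "organism": matrix.columns,
            "t": t,
            "p": p,
            "logfc": a.mean(axis=1) - b.mean(axis=1),
        }
    )


def linkage_to_newick(linkage: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)
    names = [str(n) for n in leaf_names]

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({build(tree.left, tree.dist)},{build(tree.right, tree.dist)});"


def linkage_table(linkage: np.ndarray) -> pd.DataFrame:
    """Linkage record as a table (child ids, merge height, cluster size)."""
    return pd.DataFrame(
        {
            "child_a": linkage[:, 0].astype(int),
            "child_b": linkage[:, 1].astype(int),
            "height": linkage[:, 2],
            "size": linkage[:, 3].astype(int),
        }
    )
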