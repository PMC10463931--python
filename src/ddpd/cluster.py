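"""Hierarchical clustering of descriptor or RMSF vectors for variant discrimination.

Distances are Euclidean over the "non-null bits": positions that are zero in
every compared vector (MSA gap columns of rs3DDPDs, unresolved positions of
mapped RMSF profiles) are removed before the pairwise distances are computed,
so shared padding never dilutes the metric.  Trees are agglomerative
(average linkage by default) and flat clusters come from cutting at a
fraction of the final merge distance (70% in the standard analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "LinkageTree",
    "descriptor_distance_matrix",
    "hierarchical_cluster",
    "cut_clusters",
]


def descriptor_distance_matrix(
    vectors: Mapping[str, np.ndarray],
) -> tuple[list[str], np.ndarray]:
    """Pairwise Euclidean distances over columns that are non-zero somewhere.

    Returns ``(labels, D)`` with labels in input order.  Removing columns that
    are zero across *all* vectors never changes any pairwise distance; the
    removal only makes the "non-null" semantics explicit.
    """
    labels = list(vectors)
    if len(labels) < 2:
        raise ValueError("need at least 2 vectors")
    arrs = [np.asarray(vectors[k], dtype=float) for k in labels]
    lengths = {a.shape for a in arrs}
    if len(lengths) != 1:
        raise ValueError(f"vector lengths differ: {lengths}")
    X = np.vstack(arrs)
    nonnull = np.flatnonzero((X != 0).any(axis=0))
    X = X[:, nonnull]
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(D, 0.0)
    return labels, D


@dataclass
class LinkageTree:
    """An agglomerative merge sequence over labelled leaves.

    ``Z`` is the scipy linkage matrix (merge members, merge distance, size);
    merge distances are non-decreasing for the supported linkages and the last
    row's distance is ``d_max``.
    """

    Z: np.ndarray
    labels: list[str]
    linkage_method: str

    def __post_init__(self) -> None:
        if self.Z.shape[0] != len(self.labels) - 1 and len(self.labels) > 1:
            raise ValueError("linkage matrix does not match the leaf count")

    @property
    def d_max(self) -> float:
        return float(self.Z[-1, 2]) if len(self.Z) else 0.0

    @property
    def merge_distances(self) -> np.ndarray:
        return self.Z[:, 2].copy()


def hierarchical_cluster(
    dist: np.ndarray, labels: list[str], linkage: str = "average"
) -> LinkageTree:
    """Agglomerative clustering of a symmetric distance matrix.

    Average linkage (UPGMA) by default; the method is configurable and
    recorded on the tree since flat clusters can differ by linkage.  Ties are
    resolved deterministically by scipy's stable merge order, i.e. by input
    (label) order.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if (D < 0).any():
        raise ValueError("negative distances")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) != D.shape[0]:
        raise ValueError("labels do not match the matrix size")
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return LinkageTree(Z=Z, labels=list(labels), linkage_method=linkage)


def cut_clusters(tree: LinkageTree, fraction: float = 0.7) -> dict[str, int]:
    """Flat clusters from cutting the tree at ``fraction * d_max``.

    Cluster ids are 1-based (scipy convention).  A single-leaf tree is one
    cluster; ``fraction=1`` cuts at the final merge itself.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(tree.labels) == 1:
        return {tree.labels[0]: 1}
    assignments = hierarchy.fcluster(
        tree.Z, t=fraction * tree.d_max, criterion="distance"
    )
    return dict(zip(tree.labels, (int(c) for c in assignments)))


def plot_dendrogram(tree: LinkageTree, fraction: float = 0.7, ax=None):
    """Dendrogram with the cut height marked; returns the matplotlib axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    hierarchy.dendrogram(
        tree.Z, labels=tree.labels, ax=ax, color_threshold=fraction * tree.d_max
    )
    ax.axhline(fraction * tree.d_max, ls="--", lw=0.8, color="grey")
    ax.set_ylabel("merge distance")
    return ax
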