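"""Variety clustering from VAF profiles.

Varieties are compared by the Euclidean distance between their VAF
profiles across variants; agglomeration uses Ward's minimum-variance
method in its ward.D2 form (squared merge costs grow by the between-
centroid variance increment), so trees match R's ``hclust(method =
"ward.D2")`` on the same distances.  Missing VAF entries are handled
pairwise-complete with rescaling to the full variant count, or by zero
imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genomic_io import SampleManifest
from .screen import VafMatrix


def vaf_distance(matrix: VafMatrix, missing: str = "rescale") -> np.ndarray:
    """Samples x samples Euclidean distance over variants.

    missing="rescale": for each pair, sum squared differences over
    mutually present variants and rescale, d = sqrt(D / m_used * m_total),
    so sparsely observed pairs stay comparable to fully observed ones.
    missing="zero": impute missing VAF as 0 and use the plain distance.
    A pair with no mutually present variant is an error naming the pair.
    """
    X = matrix.values.T.astype(float)  # samples x variants
    n, m_total = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    if missing == "zero":
        X0 = np.nan_to_num(X, nan=0.0)
        sq = np.sum(X0 ** 2, axis=1)
        D = sq[:, None] + sq[None, :] - 2 * X0 @ X0.T
        return np.sqrt(np.clip(D, 0, None))
    if missing != "rescale":
        raise ValueError("missing must be 'rescale' or 'zero'")
    present = (~np.isnan(X)).astype(float)
    X0 = np.nan_to_num(X, nan=0.0)
    m_used = present @ present.T
    off = ~np.eye(n, dtype=bool)
    if np.any(m_used[off] == 0):
        i, j = np.argwhere((m_used == 0) & off)[0]
        raise ValueError(
            f"samples {matrix.sample_order[i]!r} and {matrix.sample_order[j]!r} "
            "share no mutually observed variant")
    t1 = (X0 ** 2) @ present.T
    D = t1 + t1.T - 2 * X0 @ X0.T
    D = np.clip(D, 0, None)
    with np.errstate(invalid="ignore"):
        scaled = np.where(m_used > 0, D / m_used * m_total, 0.0)
    d = np.sqrt(scaled)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class ClusterTree:
    """Agglomeration result: a scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray  # (n-1) x 4: node_a, node_b, height, size
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage))

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster ids (1..k) for each leaf at a k-cluster cut."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"k={k} out of range [1, {self.n_leaves}]")
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        root = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(root, root.dist) + ";"


def ward_cluster(distances: np.ndarray, labels: list[str] | None = None) -> ClusterTree:
    """Ward (ward.D2) agglomeration of a distance matrix.

    Merge heights are non-decreasing; ties between equal merge costs are
    broken deterministically by scipy's nearest-neighbor chain order.
    """
    d = np.asarray(distances, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite values")
    n = d.shape[0]
    labels = labels if labels is not None else [str(i) for i in range(n)]
    Z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    return ClusterTree(Z, list(labels))


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    sample_order: list[str]
    metric: str

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_order, columns=self.sample_order)


def similarity_from_distance(
    distances: np.ndarray, sample_order: list[str] | None = None
) -> SimilarityMatrix:
    """Max-normalized complement of the distance: s = 1 - d / max(d).

    Shares the clustering geometry: identical profiles map to 1, the most
    dissimilar pair to 0.  An all-zero distance matrix yields all-ones
    similarity with a warning.
    """
    d = np.asarray(distances, dtype=float)
    dmax = d.max() if d.size else 0.0
    if dmax == 0:
        warnings.warn("all distances are zero; similarity set to 1 everywhere",
                      stacklevel=2)
        s = np.ones_like(d)
    else:
        s = 1.0 - d / dmax
    order = sample_order if sample_order is not None else [str(i) for i in range(d.shape[0])]
    return SimilarityMatrix(s, list(order), metric="1 - d/max(d), Euclidean VAF d")


def cluster_composition(
    tree: ClusterTree, k: int, manifest: SampleManifest
) -> pd.DataFrame:
    """Type composition of each cluster at a k-cluster cut of the tree.

    Purity is the majority-type fraction within the cluster.
    """
    assignments = tree.cut(k)
    type_of = {s.sample_id: s.type_label for s in manifest.samples}
    rows = []
    for cid in sorted(set(assignments)):
        members = [tree.labels[i] for i in np.flatnonzero(assignments == cid)]
        n_fiber = sum(type_of[m] == "fiber" for m in members)
        n_linseed = len(members) - n_fiber
        majority = "fiber" if n_fiber >= n_linseed else "linseed"
        purity = max(n_fiber, n_linseed) / len(members)
        rows.append((cid, len(members), n_fiber, n_linseed, majority, purity))
    return pd.DataFrame(rows, columns=[
        "cluster", "n", "n_fiber", "n_linseed", "majority_type", "purity"])
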