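"""Cell-cell distances, classical MDS, and hierarchical clustering.

The leading log-fold-change distance between two cells is the root mean
square of the k largest absolute per-gene log2 expression differences,
with the top-k set recomputed for every pair.  Classical (Torgerson) MDS
double-centers the squared distance matrix and embeds on the leading
eigenvectors with a fixed sign convention so runs are reproducible.
Hierarchical clustering is Euclidean with a configurable linkage,
delegated to scipy's agglomerative implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .normalize import ExpressionMatrix


@dataclass
class DistanceMatrix:
    d: np.ndarray
    ids: list[str]
    method: str
    k_top: int | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0) or np.any(self.d < 0):
            raise ValueError("distances must be nonnegative with zero diagonal")


@dataclass
class DendrogramResult:
    linkage_matrix: np.ndarray         # scipy linkage encoding of the merge tree
    ids: list[str]
    leaf_order: list[int]
    linkage: str
    axis: str


def leading_logfc_distances(expr: ExpressionMatrix, k_top: int = 500,
                            block: int = 64) -> DistanceMatrix:
    """Pairwise leading log2-fold-change distances between cells.

    For each pair, d = sqrt(mean of the min(k_top, n_genes) largest squared
    per-gene differences).  Computed in row blocks to bound memory.
    """
    if k_top < 1:
        raise ValueError("k_top must be >= 1")
    x = expr.values
    g, n = x.shape
    if n < 2:
        raise ValueError("need >=2 cells")
    k = min(k_top, g)
    d = np.zeros((n, n))
    for start in range(0, n, block):
        stop = min(start + block, n)
        # diffs: (stop-start, n, g)
        diffs = (x.T[start:stop, None, :] - x.T[None, :, :]) ** 2
        if k < g:
            part = np.partition(diffs, g - k, axis=2)[:, :, g - k:]
        else:
            part = diffs
        d[start:stop, :] = np.sqrt(part.mean(axis=2))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d, ids=list(expr.sample_ids), method="leading_logfc", k_top=k_top)


def classical_mds(dist: DistanceMatrix, dims: int = 2) -> np.ndarray:
    """Torgerson scaling of a distance matrix into ``dims`` coordinates.

    Negative eigenvalues (non-Euclidean input) are clamped to zero.  Each
    axis is flipped so its largest-magnitude loading is positive.
    """
    n = len(dist.ids)
    if dims > n - 1:
        raise ValueError("dims must be <= n_samples - 1")
    d2 = dist.d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.maximum(evals[order], 0.0)
    coords = evecs[:, order] * np.sqrt(lam)[None, :]
    for k in range(dims):
        i = int(np.argmax(np.abs(coords[:, k])))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def hcluster(expr: ExpressionMatrix, axis: str = "cells",
             linkage: str = "complete") -> DendrogramResult:
    """Agglomerative clustering with Euclidean distance.

    ``axis`` chooses whether genes (rows) or cells (columns) are
    clustered; gene clustering expects standardized input.
    """
    if linkage not in ("complete", "average", "ward", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if axis == "cells":
        data = expr.values.T
        ids = list(expr.sample_ids)
    elif axis == "genes":
        data = expr.values
        ids = list(expr.gene_ids)
    else:
        raise ValueError("axis must be 'genes' or 'cells'")
    if data.shape[0] < 2:
        raise ValueError("need >=2 items to cluster")
    z = hierarchy.linkage(data, method=linkage, metric="euclidean")
    leaves = hierarchy.leaves_list(z).tolist()
    return DendrogramResult(linkage_matrix=z, ids=ids, leaf_order=leaves,
                            linkage=linkage, axis=axis)


def cut_clusters(tree: DendrogramResult, k: int) -> np.ndarray:
    """Cut the dendrogram into k groups; labels are 0-based and stable."""
    n = len(tree.ids)
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    return hierarchy.cut_tree(tree.linkage_matrix, n_clusters=k).ravel()
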