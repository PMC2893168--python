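"""Entropy-based detection of outlier instances.

Each instance (column) gets an "outlier-degree": the decrease of the
matrix SVD-entropy when that instance is removed. Instances whose removal
makes the dataset more homogeneous — degree above mean + 1 SD — are
flagged. Removing column ``j`` from ``A`` deletes row and column ``j``
from the Gram matrix ``C = A^T A``, so degrees come from exact
eigendecompositions of (N-1) x (N-1) principal submatrices.

A kth-nearest-neighbour distance ranking is provided as the conventional
baseline for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from .entropy_core import (
    ExpressionMatrix,
    entropy_from_eigenvalues,
    gram_matrix,
)

__all__ = [
    "OutlierReport",
    "KnnOutlierRanking",
    "udo_degree",
    "rank_instances",
    "knn_outlier_ranking",
]


@dataclass(frozen=True)
class OutlierReport:
    """Per-instance outlier-degrees, ranking and flagged set.

    ``degrees[j] = H(A) - H(A without instance j)``; ``flagged[j]`` is
    True iff the degree strictly exceeds ``mean_degree + sd_degree``.
    ``ranks`` is a permutation of 1..N, rank 1 = highest degree, stable
    ties.
    """

    instance_ids: tuple[str, ...]
    degrees: np.ndarray
    ranks: np.ndarray
    flagged: np.ndarray
    mean_degree: float
    sd_degree: float

    def order(self) -> np.ndarray:
        return np.argsort(self.ranks, kind="stable")

    def flagged_ids(self) -> list[str]:
        return [
            self.instance_ids[j] for j in self.order() if self.flagged[j]
        ]


@dataclass(frozen=True)
class KnnOutlierRanking:
    """Instances ranked by distance to their kth nearest neighbour."""

    instance_ids: tuple[str, ...]
    distances: np.ndarray
    ranks: np.ndarray
    k: int

    def order(self) -> np.ndarray:
        return np.argsort(self.ranks, kind="stable")


def _submatrix_entropy(
    gram: np.ndarray, drop: int, norm_constant: float
) -> float:
    keep = np.arange(gram.shape[0]) != drop
    sub = gram[np.ix_(keep, keep)]
    eigvals = scipy.linalg.eigvalsh(sub)
    if np.sum(np.clip(eigvals, 0.0, None)) <= 0.0:
        raise ValueError("remaining matrix is all-zero")
    return entropy_from_eigenvalues(eigvals, norm_constant)


def udo_degree(matrix: ExpressionMatrix, instance_index: int) -> float:
    """Outlier-degree ``H(A) - H(A without instance column j)``."""
    n = matrix.n_instances
    if n < 3:
        raise ValueError("need at least 3 instances to score removals")
    if not 0 <= instance_index < n:
        raise IndexError(
            f"instance index {instance_index} out of range for N={n}"
        )
    nc = float(np.log(min(matrix.shape)))
    gram = gram_matrix(matrix)
    h_full = entropy_from_eigenvalues(scipy.linalg.eigvalsh(gram), nc)
    return h_full - _submatrix_entropy(gram, instance_index, nc)


def rank_instances(
    matrix: ExpressionMatrix, sd_flavor: str = "population"
) -> OutlierReport:
    """Outlier-degrees for all instances with mean + 1 SD flagging."""
    n = matrix.n_instances
    if n < 3:
        raise ValueError("need at least 3 instances to score removals")
    nc = float(np.log(min(matrix.shape)))
    gram = gram_matrix(matrix)
    h_full = entropy_from_eigenvalues(scipy.linalg.eigvalsh(gram), nc)
    degrees = np.array(
        [h_full - _submatrix_entropy(gram, j, nc) for j in range(n)]
    )
    order = np.argsort(-degrees, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    mean = float(degrees.mean())
    sd = float(degrees.std(ddof=0 if sd_flavor == "population" else 1))
    return OutlierReport(
        instance_ids=matrix.instance_ids,
        degrees=degrees,
        ranks=ranks,
        flagged=degrees > mean + sd,
        mean_degree=mean,
        sd_degree=sd,
    )


def knn_outlier_ranking(
    matrix: ExpressionMatrix, k: int = 5
) -> KnnOutlierRanking:
    """Rank instances by Euclidean distance to their kth nearest neighbour."""
    n = matrix.n_instances
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < N={n}")
    points = matrix.values.T
    dists = cdist(points, points)
    # column k of the sorted rows skips the zero self-distance
    kth = np.sort(dists, axis=1)[:, k]
    order = np.argsort(-kth, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return KnnOutlierRanking(
        instance_ids=matrix.instance_ids,
        distances=kth,
        ranks=ranks,
        k=k,
    )
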