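"""Baseline feature selectors and the clustering evaluation harness.

Selection baselines: per-feature variance, per-feature entropy (the same
normalized-squares formalism as the spectrum weights, applied to a single
feature's values), and uniform random selection. Quality of a selected
feature set is measured by running k-means repeatedly on the instances
restricted to those features and scoring each clustering against known
labels with the pair-counting Jaccard score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .entropy_core import ExpressionMatrix, entropy_from_weights

__all__ = [
    "EvaluationResult",
    "variance_selection",
    "feature_entropy_selection",
    "random_selection",
    "jaccard_score",
    "kmeans_jaccard_evaluation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationResult:
    """Mean/SD Jaccard of repeated k-means runs for one feature set."""

    method: str
    n_features: int
    jaccard_mean: float
    jaccard_sd: float
    k: int
    repeats: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.jaccard_mean <= 1.0:
            raise ValueError("jaccard_mean outside [0, 1]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def variance_selection(matrix: ExpressionMatrix, n: int) -> list[str]:
    """Top-n feature ids by population variance across instances."""
    _check_n(matrix, n)
    v = matrix.values.var(axis=1, ddof=0)
    order = np.argsort(-v, kind="stable")
    return [matrix.feature_ids[i] for i in order[:n]]


def per_feature_entropy(values: np.ndarray) -> np.ndarray:
    """Entropy of each feature row's normalized squared values.

    ``p_j = x_j^2 / sum_l x_l^2`` over the row, entropy normalized by
    ``log N``. All-zero rows get entropy 0 (with a logged warning): they
    carry no signal to spread.
    """
    values = np.asarray(values, dtype=np.float64)
    sq = values**2
    totals = sq.sum(axis=1)
    zero_rows = totals <= 0.0
    if np.any(zero_rows):
        logger.warning(
            "%d all-zero feature(s); their entropy is set to 0",
            int(zero_rows.sum()),
        )
    log_n = math.log(values.shape[1])
    out = np.zeros(values.shape[0])
    for i in np.nonzero(~zero_rows)[0]:
        out[i] = entropy_from_weights(sq[i] / totals[i], log_n)
    return out


def feature_entropy_selection(
    matrix: ExpressionMatrix, n: int, order: str = "low_first"
) -> list[str]:
    """Top-n feature ids by per-feature entropy, lowest first by default."""
    _check_n(matrix, n)
    if order not in ("low_first", "high_first"):
        raise ValueError(f"unknown order {order!r}")
    h = per_feature_entropy(matrix.values)
    idx = np.argsort(h if order == "low_first" else -h, kind="stable")
    return [matrix.feature_ids[i] for i in idx[:n]]


def random_selection(
    matrix: ExpressionMatrix, n: int, seed: int
) -> list[str]:
    """Uniform sample of n feature ids without replacement."""
    _check_n(matrix, n)
    rng = np.random.default_rng(seed)
    idx = rng.choice(matrix.n_features, size=n, replace=False)
    return [matrix.feature_ids[i] for i in idx]


def _check_n(matrix: ExpressionMatrix, n: int) -> None:
    if not 1 <= n <= matrix.n_features:
        raise ValueError(
            f"n={n} out of range 1..{matrix.n_features}"
        )


def jaccard_score(
    clustering: Sequence, reference: Sequence
) -> float:
    """Pair-counting Jaccard agreement between two partitions.

    Over all unordered instance pairs: ``n11`` co-clustered in both,
    ``n10``/``n01`` co-clustered in exactly one; the score is
    ``n11 / (n11 + n10 + n01)``, and 1.0 when neither partition
    co-clusters any pair at all.
    """
    a = np.asarray(clustering)
    b = np.asarray(reference)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def pairs(counts: np.ndarray) -> int:
        return int(np.sum(counts * (counts - 1) // 2))

    n11 = pairs(contingency)
    n1x = pairs(contingency.sum(axis=1))
    nx1 = pairs(contingency.sum(axis=0))
    denom = n1x + nx1 - n11  # n11 + n10 + n01
    if denom == 0:
        return 1.0
    return n11 / denom


def kmeans_jaccard_evaluation(
    matrix: ExpressionMatrix,
    labels: Sequence,
    feature_ids: Sequence[str],
    k: int,
    repeats: int = 100,
    seed: int = 0,
    method: str = "custom",
) -> EvaluationResult:
    """Repeat k-means on the selected features and score against labels.

    Instances (columns restricted to ``feature_ids`` rows) are the points;
    no preprocessing is applied. Each repeat uses a fresh k-means++
    initialization drawn from a seeded stream.
    """
    labels = np.asarray(labels)
    if labels.shape != (matrix.n_instances,):
        raise ValueError("labels length must equal the number of instances")
    if not 2 <= k <= matrix.n_instances:
        raise ValueError(f"k={k} out of range 2..N")
    if len(feature_ids) == 0:
        raise ValueError("empty feature set")
    index = {fid: i for i, fid in enumerate(matrix.feature_ids)}
    try:
        rows = [index[fid] for fid in feature_ids]
    except KeyError as exc:
        raise ValueError(f"unknown feature id {exc.args[0]!r}") from None
    points = matrix.values[rows].T
    rng = np.random.default_rng(seed)
    scores = np.empty(repeats)
    for r in range(repeats):
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=1,
            max_iter=300,
            random_state=int(rng.integers(2**31 - 1)),
        )
        assignment = km.fit_predict(points)
        scores[r] = jaccard_score(assignment, labels)
    return EvaluationResult(
        method=method,
        n_features=len(feature_ids),
        jaccard_mean=float(scores.mean()),
        jaccard_sd=float(scores.std(ddof=0)),
        k=k,
        repeats=repeats,
    )
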