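"""Dataset-applicability criteria for entropy-based feature filtering.

Two entropy-like measures decide whether a dataset is amenable to the
leave-one-out ranking: SE, on the normalized squares of the feature
scores, and VE, on the feature variances. Both lie in [0, 1] and equal 1
only for a flat profile. Their geometric mean below a threshold (default
0.8) marks the dataset as suitable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .entropy_core import (
    ExpressionMatrix,
    entropy_from_weights,
    matrix_entropy,
)
from .uff_exact import FeatureScoreTable
from .uff_fast import DEFAULT_WARN_THRESHOLD

__all__ = [
    "ApplicabilityReport",
    "score_entropy_SE",
    "variance_entropy_VE",
    "applicability_report",
    "DEFAULT_APPLICABILITY_THRESHOLD",
]

DEFAULT_APPLICABILITY_THRESHOLD = 0.8


@dataclass(frozen=True)
class ApplicabilityReport:
    """SE/VE measures, their combination, and the suitability verdict."""

    SE: float
    VE: float
    combined: float
    suitable: bool
    matrix_entropy: float
    fast_warning: bool
    threshold: float = DEFAULT_APPLICABILITY_THRESHOLD


def score_entropy_SE(scores: np.ndarray) -> float:
    """Normalized entropy of the squared feature scores.

    ``p_i = score_i^2 / sum_j score_j^2``; SE is the Shannon entropy of
    ``p`` divided by ``log M``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 2:
        raise ValueError("need at least 2 scores")
    sq = scores**2
    total = sq.sum()
    if total <= 0.0:
        raise ValueError("all scores are zero; SE undefined")
    return entropy_from_weights(sq / total, math.log(scores.size))


def variance_entropy_VE(
    matrix: ExpressionMatrix, variance_flavor: str = "population"
) -> float:
    """Normalized entropy of the per-feature variances across instances."""
    if variance_flavor not in ("population", "sample"):
        raise ValueError(f"unknown variance_flavor {variance_flavor!r}")
    ddof = 0 if variance_flavor == "population" else 1
    v = matrix.values.var(axis=1, ddof=ddof)
    total = v.sum()
    if total <= 0.0:
        raise ValueError("all features are constant; VE undefined")
    return entropy_from_weights(v / total, math.log(matrix.n_features))


def applicability_report(
    matrix: ExpressionMatrix,
    table: FeatureScoreTable,
    threshold: float = DEFAULT_APPLICABILITY_THRESHOLD,
    warn_threshold: float = DEFAULT_WARN_THRESHOLD,
) -> ApplicabilityReport:
    """Assemble the applicability verdict for a matrix and its score table.

    ``suitable`` is True when ``sqrt(SE * VE)`` lies strictly below the
    threshold.
    """
    se = score_entropy_SE(table.scores)
    ve = variance_entropy_VE(matrix)
    combined = math.sqrt(se * ve)
    h = (
        table.matrix_entropy
        if table.matrix_entropy is not None
        else matrix_entropy(matrix)
    )
    return ApplicabilityReport(
        SE=se,
        VE=ve,
        combined=combined,
        suitable=combined < threshold,
        matrix_entropy=h,
        fast_warning=h > warn_threshold,
        threshold=threshold,
    )
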