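"""Singular spectra and SVD-entropy.

The quantities computed here are shared by every other module: the singular
values of a feature-by-instance matrix, their normalized squared weights,
the Shannon-form entropy of those weights scaled into [0, 1], and the Gram
matrix route (``C = A^T A``) whose eigenvalues are the squared singular
values of ``A``.

All entropies are computed in natural log; the base cancels after division
by the normalization constant ``log(q)`` with ``q = min(M, N)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "ExpressionMatrix",
    "SingularSpectrum",
    "singular_spectrum",
    "svd_entropy",
    "entropy_from_weights",
    "entropy_from_eigenvalues",
    "matrix_entropy",
    "gram_matrix",
    "gram_eigendecomposition",
    "spectral_objective",
]

# weights below this are treated as exact zeros before taking logs
WEIGHT_FLOOR = 1e-15

OBJECTIVES = ("svd_entropy", "neg_sum_squares", "geometric_mean")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A numeric M-features x N-instances matrix with row/column identifiers.

    Parameters
    ----------
    values
        Real matrix, shape ``(M, N)``; rows are features (e.g. genes),
        columns are instances (e.g. samples). All entries must be finite
        and at least one must be nonzero.
    feature_ids
        ``M`` unique row identifiers.
    instance_ids
        ``N`` unique column identifiers.
    """

    values: np.ndarray
    feature_ids: tuple[str, ...]
    instance_ids: tuple[str, ...]

    def __init__(
        self,
        values: np.ndarray,
        feature_ids: Sequence[str],
        instance_ids: Sequence[str],
    ) -> None:
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        m, n = values.shape
        if m < 2 or n < 2:
            raise ValueError(f"matrix must be at least 2x2, got {m}x{n}")
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix contains non-finite entries (NaN/Inf)")
        if not np.any(values):
            raise ValueError("matrix is identically zero")
        feature_ids = tuple(str(x) for x in feature_ids)
        instance_ids = tuple(str(x) for x in instance_ids)
        if len(feature_ids) != m:
            raise ValueError(
                f"{len(feature_ids)} feature ids for {m} rows"
            )
        if len(instance_ids) != n:
            raise ValueError(
                f"{len(instance_ids)} instance ids for {n} columns"
            )
        if len(set(feature_ids)) != m:
            raise ValueError("duplicate feature ids")
        if len(set(instance_ids)) != n:
            raise ValueError("duplicate instance ids")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", feature_ids)
        object.__setattr__(self, "instance_ids", instance_ids)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_instances(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def drop_feature(self, index: int) -> "ExpressionMatrix":
        """Matrix with feature row ``index`` removed."""
        m = self.n_features
        if not 0 <= index < m:
            raise IndexError(f"feature index {index} out of range for M={m}")
        keep = np.arange(m) != index
        return ExpressionMatrix(
            self.values[keep],
            [fid for i, fid in enumerate(self.feature_ids) if keep[i]],
            self.instance_ids,
        )

    def drop_instance(self, index: int) -> "ExpressionMatrix":
        """Matrix with instance column ``index`` removed."""
        n = self.n_instances
        if not 0 <= index < n:
            raise IndexError(f"instance index {index} out of range for N={n}")
        keep = np.arange(n) != index
        return ExpressionMatrix(
            self.values[:, keep],
            self.feature_ids,
            [iid for j, iid in enumerate(self.instance_ids) if keep[j]],
        )


@dataclass(frozen=True)
class SingularSpectrum:
    """Ordered singular values of a matrix and their normalized weights.

    ``weights[k] = s_k**2 / sum_j s_j**2`` and ``norm_constant = log(q)``
    with ``q = min(M, N)``; the same constant is reused for all
    leave-one-out entropies derived from the matrix.
    """

    singular_values: np.ndarray
    weights: np.ndarray
    q: int
    norm_constant: float = field(default=0.0)

    def __post_init__(self) -> None:
        s = np.asarray(self.singular_values, dtype=np.float64)
        w = np.asarray(self.weights, dtype=np.float64)
        if s.shape != (self.q,) or w.shape != (self.q,):
            raise ValueError("singular_values and weights must have length q")
        if np.any(s < 0):
            raise ValueError("singular values must be non-negative")
        if np.any(np.diff(s) > 1e-12 * max(s[0], 1.0)):
            raise ValueError("singular values must be non-increasing")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "singular_values", s)
        object.__setattr__(self, "weights", w)


def singular_spectrum(matrix: ExpressionMatrix) -> SingularSpectrum:
    """Singular values of the matrix and their normalized squared weights."""
    s = np.linalg.svd(matrix.values, compute_uv=False)
    total = float(np.sum(s**2))
    if total <= 0.0:
        raise ValueError("zero matrix has no defined spectrum weights")
    q = min(matrix.shape)
    return SingularSpectrum(
        singular_values=s,
        weights=s**2 / total,
        q=q,
        norm_constant=float(np.log(q)),
    )


def entropy_from_weights(weights: np.ndarray, norm_constant: float) -> float:
    """Shannon entropy of a weight vector divided by ``norm_constant``.

    ``0 * log 0`` is taken as 0; weights below ``WEIGHT_FLOOR`` are treated
    as zeros before the log.
    """
    if norm_constant <= 0.0:
        raise ValueError("entropy undefined for rank-bound 1")
    w = np.asarray(weights, dtype=np.float64)
    w = w[w > WEIGHT_FLOOR]
    h = float(-np.sum(w * np.log(w)) / norm_constant)
    # round-off can push the result a hair outside [0, 1]
    return min(max(h, 0.0), 1.0)


def entropy_from_eigenvalues(
    eigenvalues: np.ndarray, norm_constant: float
) -> float:
    """Entropy of Gram-matrix eigenvalues after normalization to weights.

    Tiny negative eigenvalues from round-off are clipped to zero first.
    """
    c = np.clip(np.asarray(eigenvalues, dtype=np.float64), 0.0, None)
    total = c.sum()
    if total <= 0.0:
        raise ValueError("zero spectrum has no defined entropy")
    return entropy_from_weights(c / total, norm_constant)


def svd_entropy(spectrum: SingularSpectrum) -> float:
    """SVD-entropy ``H`` in [0, 1]: 0 = rank one, 1 = flat spectrum."""
    if spectrum.q == 1:
        raise ValueError("entropy undefined for rank-bound 1")
    return entropy_from_weights(spectrum.weights, spectrum.norm_constant)


def matrix_entropy(matrix: ExpressionMatrix) -> float:
    """Convenience: SVD-entropy of the full matrix."""
    return svd_entropy(singular_spectrum(matrix))


def gram_matrix(matrix: ExpressionMatrix) -> np.ndarray:
    """The N x N Gram matrix ``C = A^T A`` (symmetrized against round-off)."""
    a = matrix.values
    c = a.T @ a
    return (c + c.T) / 2.0


def gram_eigendecomposition(
    gram: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (non-increasing, clipped at 0) and eigenvectors of ``C``.

    Returns ``(c, V)`` with ``V`` orthonormal columns ordered to match
    ``c``; ``c[i]`` equals the squared i-th singular value of the matrix
    whose Gram matrix was supplied.
    """
    gram = np.asarray(gram, dtype=np.float64)
    if gram.ndim != 2 or gram.shape[0] != gram.shape[1]:
        raise ValueError("gram matrix must be square")
    scale = max(float(np.abs(gram).max()), 1.0)
    if np.abs(gram - gram.T).max() > 1e-8 * scale:
        raise ValueError("gram matrix must be symmetric")
    c, v = scipy.linalg.eigh(gram)
    order = np.argsort(c)[::-1]
    c = np.clip(c[order], 0.0, None)
    return c, v[:, order]


def spectral_objective(spectrum: SingularSpectrum, objective: str) -> float:
    """A monotone objective on the spectrum weights.

    ``svd_entropy`` (default elsewhere), ``neg_sum_squares`` and
    ``geometric_mean`` are all maximal at the uniform spectrum and minimal
    at a single-mass spectrum.
    """
    w = spectrum.weights
    if objective == "svd_entropy":
        return svd_entropy(spectrum)
    if objective == "neg_sum_squares":
        return float(-np.sum(w**2))
    if objective == "geometric_mean":
        if np.any(w <= WEIGHT_FLOOR):
            return 0.0
        return float(np.exp(np.mean(np.log(w))))
    raise ValueError(
        f"unknown objective {objective!r}; expected one of {OBJECTIVES}"
    )
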