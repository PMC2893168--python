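"""Seeded generators of planted feature-by-instance matrices.

The planted matrix reproduces the structure the entropy-based filter
assumes in expression data:

* a shared positive baseline on every feature, creating a dominant first
  principal component;
* a minority of *informative* features carrying cluster-specific mean
  shifts (high mean and variance, projections spread over several
  components) — the features the filter should select;
* a minority of *pc1-noise* features: a large random amplitude times an
  all-ones instance profile plus wide Gaussian noise, so nearly all of
  their mass sits on the first component — the features the filter should
  push into the negative group;
* a majority of low-variance neutral features.

Ground truth (feature roles, cluster labels, injected outliers) is
returned alongside the matrix so every downstream test can assert against
it. Values are clipped at 0 after assembly (intensity-like data); the
default scales make clipping rare.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .entropy_core import ExpressionMatrix

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "generate_planted_matrix",
    "inject_outlier_instances",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-matrix generator.

    The defaults are tuned so the generated matrix sits in the regime the
    fast approximation requires (full-matrix SVD-entropy < 0.1) while the
    planted groups are recoverable by the exact filter.
    """

    M: int = 2000
    N: int = 60
    n_clusters: int = 3
    n_informative: int = 100
    n_pc1_noise: int = 100
    baseline_offset: float = 10.0
    informative_amplitude: float = 10.0
    noise_sd: float = 0.5
    outlier_shift: float = 100.0
    n_outliers: int = 0
    seed: int = 1
    # amplitude of the pc1-noise features, in units of baseline_offset
    pc1_amplitude_range: tuple[float, float] = (6.0, 10.0)
    # noise width of the pc1-noise features, in units of baseline_offset
    pc1_noise_scale: float = 0.25

    def __post_init__(self) -> None:
        if self.M < 2 or self.N < 2:
            raise ValueError("need M >= 2 and N >= 2")
        if self.n_informative < 0 or self.n_pc1_noise < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_informative + self.n_pc1_noise > self.M:
            raise ValueError("planted feature counts exceed M")
        if not 0 <= self.n_outliers < self.N:
            raise ValueError("n_outliers must satisfy 0 <= n_outliers < N")
        if self.n_clusters < 1 or self.n_clusters > self.N:
            raise ValueError("n_clusters out of range")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth accompanying a generated matrix."""

    informative_ids: tuple[str, ...]
    pc1_noise_ids: tuple[str, ...]
    neutral_ids: tuple[str, ...]
    cluster_labels: np.ndarray
    outlier_ids: tuple[str, ...] = field(default=())


def generate_planted_matrix(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Generate a planted matrix plus its ground truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    m, n = spec.M, spec.N
    b = spec.baseline_offset

    # balanced cluster assignment of instances, shuffled
    cluster_labels = rng.permutation(np.arange(n) % spec.n_clusters)

    # feature roles at shuffled row positions
    roles = np.array(
        ["informative"] * spec.n_informative
        + ["pc1_noise"] * spec.n_pc1_noise
        + ["neutral"] * (m - spec.n_informative - spec.n_pc1_noise)
    )
    roles = roles[rng.permutation(m)]

    values = b + rng.normal(0.0, spec.noise_sd, size=(m, n))

    informative_rows = np.nonzero(roles == "informative")[0]
    for j, i in enumerate(informative_rows):
        # spread planted features evenly over the clusters
        target = j % spec.n_clusters
        values[i, cluster_labels == target] += spec.informative_amplitude

    pc1_rows = np.nonzero(roles == "pc1_noise")[0]
    lo, hi = spec.pc1_amplitude_range
    amplitudes = b * rng.uniform(lo, hi, size=pc1_rows.size)
    wide_sd = b * spec.pc1_noise_scale
    for amp, i in zip(amplitudes, pc1_rows):
        values[i] = b + amp + rng.normal(0.0, wide_sd, size=n)

    np.clip(values, 0.0, None, out=values)

    width = len(str(m))
    feature_ids = [f"F{i:0{width}d}" for i in range(m)]
    instance_ids = [f"S{j:0{len(str(n))}d}" for j in range(n)]
    matrix = ExpressionMatrix(values, feature_ids, instance_ids)
    truth = PlantedTruth(
        informative_ids=tuple(feature_ids[i] for i in informative_rows),
        pc1_noise_ids=tuple(feature_ids[i] for i in pc1_rows),
        neutral_ids=tuple(
            feature_ids[i] for i in np.nonzero(roles == "neutral")[0]
        ),
        cluster_labels=cluster_labels,
    )

    if spec.n_outliers > 0:
        matrix, outlier_ids = inject_outlier_instances(
            matrix, spec.n_outliers, spec.outlier_shift, spec.seed + 1
        )
        truth = PlantedTruth(
            informative_ids=truth.informative_ids,
            pc1_noise_ids=truth.pc1_noise_ids,
            neutral_ids=truth.neutral_ids,
            cluster_labels=truth.cluster_labels,
            outlier_ids=tuple(outlier_ids),
        )
    return matrix, truth


def inject_outlier_instances(
    matrix: ExpressionMatrix,
    n_outliers: int,
    outlier_shift: float,
    seed: int,
) -> tuple[ExpressionMatrix, list[str]]:
    """Shift chosen instance columns along random off-leading directions.

    Each selected column is moved by ``outlier_shift`` along a random
    direction orthogonal to the matrix's leading left-singular vector, so
    the injected outliers open up new spectral directions rather than
    stretching the existing dominant one.
    """
    n = matrix.n_instances
    if not 0 <= n_outliers < n / 2:
        raise ValueError("n_outliers must be < N/2")
    if n_outliers == 0:
        return matrix, []
    if outlier_shift == 0.0:
        warnings.warn(
            "outlier_shift is 0: injected outliers are undetectable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    columns = rng.choice(n, size=n_outliers, replace=False)
    u1 = np.linalg.svd(matrix.values, full_matrices=False)[0][:, 0]
    values = matrix.values.copy()
    for j in columns:
        d = rng.normal(size=matrix.n_features)
        d -= (d @ u1) * u1
        d /= np.linalg.norm(d)
        values[:, j] += outlier_shift * d
    np.clip(values, 0.0, None, out=values)
    shifted = ExpressionMatrix(
        values, matrix.feature_ids, matrix.instance_ids
    )
    return shifted, [matrix.instance_ids[j] for j in sorted(columns)]
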