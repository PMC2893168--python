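"""Readers and writers for matrices, labels and result tables.

The matrix format is plain tab-delimited text: a header row of instance
ids (first cell ignored or blank) and one row per feature, feature id
first. Score and outlier tables are TSV with ``#``-prefixed header lines
recording how they were produced, so a written table can be read back
into an identical object.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .applicability import ApplicabilityReport
from .entropy_core import ExpressionMatrix
from .udo import OutlierReport
from .uff_exact import FeatureScoreTable

__all__ = [
    "RunConfig",
    "read_matrix",
    "read_labels",
    "write_score_table",
    "read_score_table",
    "write_outlier_report",
    "write_applicability_report",
    "read_config",
]


@dataclasses.dataclass
class RunConfig:
    """Run-wide options shared by the CLI subcommands."""

    method: str = "exact"
    warn_threshold: float = 0.1
    applicability_threshold: float = 0.8
    sd_flavor: str = "population"
    transpose_input: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.method not in ("exact", "fast"):
            raise ValueError(f"unknown method {self.method!r}")
        if not 0.0 < self.warn_threshold <= 1.0:
            raise ValueError("warn_threshold must lie in (0, 1]")
        if not 0.0 < self.applicability_threshold <= 1.0:
            raise ValueError("applicability_threshold must lie in (0, 1]")
        if self.sd_flavor not in ("population", "sample"):
            raise ValueError(f"unknown sd_flavor {self.sd_flavor!r}")


_CONFIG_FIELDS = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def read_config(path: str | Path) -> dict:
    """Parse a ``key = value`` config file into RunConfig keyword args."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in _CONFIG_FIELDS:
            raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
        if key in ("warn_threshold", "applicability_threshold"):
            out[key] = float(value)
        elif key == "seed":
            out[key] = int(value)
        elif key == "transpose_input":
            out[key] = value.lower() in ("1", "true", "yes")
        else:
            out[key] = value
    return out


def read_matrix(
    path: str | Path, delimiter: str = "\t", transpose: bool = False
) -> ExpressionMatrix:
    """Read a feature-by-instance matrix from delimited text.

    First row: instance ids; first column: feature ids. ``transpose=True``
    swaps the roles for files stored instances-in-rows.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, sep=delimiter, index_col=0, header=0, dtype=str,
        comment=None, skip_blank_lines=True,
    )
    if frame.shape[0] < 1 or frame.shape[1] < 1:
        raise ValueError(f"{path}: matrix has no data rows or columns")
    row_ids = [str(x) for x in frame.index]
    col_ids = [str(x) for x in frame.columns]
    if len(set(row_ids)) != len(row_ids):
        raise ValueError(f"{path}: duplicate row identifiers")
    if len(set(col_ids)) != len(col_ids):
        raise ValueError(f"{path}: duplicate column identifiers")
    values = np.empty(frame.shape, dtype=np.float64)
    raw = frame.to_numpy()
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            cell = raw[i, j]
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError
                values[i, j] = float(cell)
                if not np.isfinite(values[i, j]):
                    raise ValueError
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric or missing value {cell!r} at "
                    f"row {row_ids[i]!r}, column {col_ids[j]!r}"
                ) from None
    if transpose:
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError(
            f"{path}: need at least 2 features and 2 instances, got "
            f"{values.shape[0]}x{values.shape[1]}"
        )
    return ExpressionMatrix(values, row_ids, col_ids)


def read_labels(path: str | Path, instance_ids) -> np.ndarray:
    """Read a two-column TSV ``instance_id<TAB>label``, aligned to ids."""
    path = Path(path)
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        if parts[0] in mapping:
            raise ValueError(f"{path}:{lineno}: duplicate instance {parts[0]!r}")
        mapping[parts[0]] = parts[1]
    missing = [iid for iid in instance_ids if iid not in mapping]
    if missing:
        raise ValueError(f"{path}: no label for instance(s) {missing[:5]}")
    return np.array([mapping[iid] for iid in instance_ids])


def _format_float(x: float) -> str:
    return repr(float(x))


def write_score_table(
    table: FeatureScoreTable, path: str | Path, timestamp: str | None = None
) -> None:
    """Write a score table as TSV with ``#`` metadata header lines."""
    path = Path(path)
    lines = []
    if timestamp is not None:
        lines.append(f"# written: {timestamp}")
    lines.append(f"# method: {table.method}")
    if table.matrix_entropy is not None:
        lines.append(f"# matrix_entropy: {_format_float(table.matrix_entropy)}")
    if table.warning is not None:
        lines.append(f"# fast_warning: {str(table.warning).lower()}")
    lines.append(f"# mean_score: {_format_float(table.mean_score)}")
    lines.append(f"# sd_score: {_format_float(table.sd_score)}")
    lines.append(f"# sd_flavor: {table.sd_flavor}")
    lines.append("rank\tfeature_id\tscore\tgroup")
    for i in table.order():
        lines.append(
            f"{table.ranks[i]}\t{table.feature_ids[i]}\t"
            f"{_format_float(table.scores[i])}\t{table.groups[i]}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_score_table(path: str | Path) -> FeatureScoreTable:
    """Read back a table written by :func:`write_score_table`.

    The original input row order is not recorded in the file, so the
    returned table lists features in rank order; per-feature content and
    metadata are reproduced exactly.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    for raw in path.read_text().splitlines():
        if raw.startswith("#"):
            key, _, value = raw[1:].partition(":")
            meta[key.strip()] = value.strip()
        elif raw and not raw.startswith("rank\t"):
            rows.append(raw.split("\t"))
    if not rows:
        raise ValueError(f"{path}: empty score table")
    rows.sort(key=lambda r: int(r[0]))
    ranks = np.array([int(r[0]) for r in rows])
    warning = None
    if "fast_warning" in meta:
        warning = meta["fast_warning"] == "true"
    return FeatureScoreTable(
        feature_ids=tuple(r[1] for r in rows),
        scores=np.array([float(r[2]) for r in rows]),
        ranks=ranks,
        groups=tuple(r[3] for r in rows),
        mean_score=float(meta["mean_score"]),
        sd_score=float(meta["sd_score"]),
        method=meta["method"],
        matrix_entropy=(
            float(meta["matrix_entropy"]) if "matrix_entropy" in meta else None
        ),
        warning=warning,
        sd_flavor=meta.get("sd_flavor", "population"),
    )


def write_outlier_report(
    report: OutlierReport,
    path: str | Path,
    knn=None,
    timestamp: str | None = None,
) -> None:
    """Write an outlier report as TSV; optional kth-NN comparison columns."""
    path = Path(path)
    lines = []
    if timestamp is not None:
        lines.append(f"# written: {timestamp}")
    lines.append(f"# mean_degree: {_format_float(report.mean_degree)}")
    lines.append(f"# sd_degree: {_format_float(report.sd_degree)}")
    header = "rank\tinstance_id\tdegree\tflagged"
    if knn is not None:
        header += f"\tknn{knn.k}_distance\tknn{knn.k}_rank"
    lines.append(header)
    knn_index = (
        {iid: j for j, iid in enumerate(knn.instance_ids)} if knn else None
    )
    for j in report.order():
        row = (
            f"{report.ranks[j]}\t{report.instance_ids[j]}\t"
            f"{_format_float(report.degrees[j])}\t"
            f"{str(bool(report.flagged[j])).lower()}"
        )
        if knn is not None:
            jj = knn_index[report.instance_ids[j]]
            row += f"\t{_format_float(knn.distances[jj])}\t{knn.ranks[jj]}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def write_applicability_report(
    report: ApplicabilityReport, path: str | Path
) -> None:
    """Write an applicability report as a two-column TSV."""
    verdict = "suitable" if report.suitable else "not_suitable"
    lines = [
        "measure\tvalue",
        f"SE\t{_format_float(report.SE)}",
        f"VE\t{_format_float(report.VE)}",
        f"combined\t{_format_float(report.combined)}",
        f"threshold\t{_format_float(report.threshold)}",
        f"verdict\t{verdict}",
        f"matrix_entropy\t{_format_float(report.matrix_entropy)}",
        f"fast_warning\t{str(report.fast_warning).lower()}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
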