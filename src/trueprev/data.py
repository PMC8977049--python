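"""Survey-count containers and table input.

A prevalence survey reduces to counts: ``y`` test-positives out of
``n`` sampled subjects, either for one population or one row per
cluster (herd, study site, region).  Multi-population tables are read
from CSV or xlsx files that contain, at minimum, columns named
``positive`` and ``n`` (case-insensitive); any further columns are
carried along as labels/metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SurveyCounts", "ClusterTable", "DataError", "read_cluster_table"]

REQUIRED_COLUMNS = ("positive", "n")


class DataError(ValueError):
    """Raised for malformed survey data."""


@dataclass(frozen=True)
class SurveyCounts:
    """``y`` test-positives out of ``n`` sampled subjects."""

    y: int
    n: int

    def __post_init__(self) -> None:
        if int(self.y) != self.y or int(self.n) != self.n:
            raise DataError(f"counts must be integers, got y={self.y}, n={self.n}")
        if self.n <= 0:
            raise DataError(f"sample size must be positive, got n={self.n}")
        if not 0 <= self.y <= self.n:
            raise DataError(f"need 0 <= y <= n, got y={self.y}, n={self.n}")

    @property
    def apparent_prevalence(self) -> float:
        return self.y / self.n


@dataclass(frozen=True)
class ClusterTable:
    """Counts for k clusters, in file/row order.

    ``labels`` identify clusters in summaries and exports; ``metadata``
    optionally carries any extra input columns, indexed like the rows.
    """

    labels: tuple[str, ...]
    y: np.ndarray
    n: np.ndarray
    metadata: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=int)
        n = np.asarray(self.n, dtype=int)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "n", n)
        if y.ndim != 1 or y.shape != n.shape or len(self.labels) != y.size:
            raise DataError("labels, y and n must be one-dimensional and equally long")
        if y.size < 1:
            raise DataError("a cluster table needs at least one row")
        if np.any(n <= 0):
            raise DataError("all cluster sample sizes must be positive")
        bad = np.flatnonzero((y < 0) | (y > n))
        if bad.size:
            raise DataError(
                f"row {bad[0] + 1} ({self.labels[bad[0]]}): need 0 <= positive <= n, "
                f"got positive={y[bad[0]]}, n={n[bad[0]]}"
            )

    @property
    def k(self) -> int:
        return self.y.size

    @property
    def apparent_prevalence(self) -> np.ndarray:
        return self.y / self.n

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"label": self.labels, "positive": self.y, "n": self.n})
        if self.metadata is not None:
            for c in self.metadata.columns:
                df[c] = self.metadata[c].to_numpy()
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "table") -> "ClusterTable":
        cols = {}
        for c in df.columns:
            key = str(c).strip().lower()
            if key in REQUIRED_COLUMNS:
                if key in cols:
                    raise DataError(f"{source}: duplicate required column {key!r}")
                cols[key] = c
        for key in REQUIRED_COLUMNS:
            if key not in cols:
                raise DataError(
                    f"{source}: missing required column {key!r} "
                    f"(found: {', '.join(map(str, df.columns))})"
                )
        y_raw = df[cols["positive"]]
        n_raw = df[cols["n"]]
        for name, col in (("positive", y_raw), ("n", n_raw)):
            num = pd.to_numeric(col, errors="coerce")
            bad = np.flatnonzero(num.isna().to_numpy() | (num.to_numpy() % 1 != 0))
            if bad.size:
                raise DataError(
                    f"{source}, row {bad[0] + 1}: column {name!r} must hold "
                    f"non-negative integers, got {col.iloc[bad[0]]!r}"
                )
        y = y_raw.to_numpy(dtype=int)
        n = n_raw.to_numpy(dtype=int)
        if np.any(y < 0):
            row = int(np.flatnonzero(y < 0)[0])
            raise DataError(f"{source}, row {row + 1}: negative count {y[row]}")
        if np.any(n <= 0):
            row = int(np.flatnonzero(n <= 0)[0])
            raise DataError(f"{source}, row {row + 1}: sample size must be positive")
        bad = np.flatnonzero(y > n)
        if bad.size:
            raise DataError(
                f"{source}, row {bad[0] + 1}: positive={y[bad[0]]} exceeds n={n[bad[0]]}"
            )
        extra = [c for c in df.columns if c not in (cols["positive"], cols["n"])]
        meta = df[extra].reset_index(drop=True) if extra else None
        if extra:
            labels = tuple(str(v) for v in df[extra[0]])
        else:
            labels = tuple(str(i + 1) for i in range(len(df)))
        return cls(labels=labels, y=y, n=n, metadata=meta)


def read_cluster_table(path: str | Path, format: str | None = None) -> ClusterTable:
    """Read a multi-population count table from CSV or a spreadsheet.

    Column headers are matched case-insensitively after whitespace
    trimming; ``positive`` and ``n`` are required, duplicates of either
    are an error, and every row is validated (integer counts,
    ``0 <= positive <= n``) with row-numbered messages.  Rows keep file
    order.
    """
    path = Path(path)
    if format is None:
        format = "spreadsheet" if path.suffix.lower() in (".xls", ".xlsx") else "csv"
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "spreadsheet":
        df = pd.read_excel(path)
    else:
        raise DataError(f"unknown table format {format!r}")
    return ClusterTable.from_frame(df, source=path.name)
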