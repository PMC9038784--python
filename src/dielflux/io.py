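"""Tab-delimited table formats and the in-memory feature matrix.

All tables are UTF-8, tab-delimited, '.' decimal, one header row.  Sample
columns are named ``t{HH}_rep{j}`` where ``HH`` is elapsed hours from the
first sample (0-based) and ``j`` the replicate.  Per-sample cell counts
travel inside the table as a reserved row ``cell_count`` so that a single
file is a complete analysis input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import parse_sample_label

__all__ = ["FeatureMatrix", "read_feature_table", "write_feature_table", "CELL_ROW"]

#: Reserved feature id carrying per-sample cell counts.
CELL_ROW = "cell_count"


@dataclass
class FeatureMatrix:
    """Features × samples table with per-sample cell counts.

    ``values`` holds intensities or read counts (non-negative); ``cell_counts``
    is indexed like the columns of ``values``.
    """

    values: pd.DataFrame
    cell_counts: pd.Series

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.cell_counts.index):
            raise ValueError("cell_counts index must match sample columns")
        if (self.values.values < 0).any():
            bad = np.argwhere(self.values.values < 0)[0]
            raise ValueError(
                f"negative value at feature {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if (self.cell_counts <= 0).any():
            bad = self.cell_counts.index[self.cell_counts <= 0][0]
            raise ValueError(f"non-positive cell count in sample {bad!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")

    # -- sample bookkeeping -------------------------------------------------

    @property
    def sample_times(self) -> np.ndarray:
        """Elapsed hours of each sample column."""
        return np.array([parse_sample_label(c)[0] for c in self.values.columns])

    @property
    def replicates(self) -> np.ndarray:
        return np.array([parse_sample_label(c)[1] for c in self.values.columns])

    @property
    def timepoints(self) -> np.ndarray:
        """Sorted unique elapsed times."""
        return np.unique(self.sample_times)

    def timepoint_means(self, values: pd.DataFrame | None = None) -> pd.DataFrame:
        """Average replicate columns, one column per timepoint."""
        vals = self.values if values is None else values
        groups = vals.T.groupby(self.sample_times)
        out = groups.mean().T
        out.columns = [f"t{int(round(t)):02d}" for t in out.columns]
        return out

    def per_cell(self) -> pd.DataFrame:
        """Values normalised to the per-sample cell counts."""
        return self.values / self.cell_counts

    # -- round trip ---------------------------------------------------------

    def to_tsv(self, path) -> None:
        write_feature_table(self, path)


def write_feature_table(matrix: FeatureMatrix, path) -> None:
    path = Path(path)
    table = pd.concat([matrix.cell_counts.to_frame(CELL_ROW).T, matrix.values])
    table.index.name = "feature_id"
    table.to_csv(path, sep="\t", float_format="%.17g")


def read_feature_table(path) -> FeatureMatrix:
    """Read and validate a feature table written by :func:`write_feature_table`.

    Rejects ragged rows, negative values, duplicate feature ids and missing
    or malformed sample labels, naming the offending location.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", index_col=0,
                            float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed table: {exc}") from exc
    if table.isna().any().any():
        row = table.index[table.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value in row {row!r}")
    for col in table.columns:
        parse_sample_label(col)
    if CELL_ROW not in table.index:
        raise ValueError(f"{path}: reserved row {CELL_ROW!r} not found")
    cells = table.loc[CELL_ROW].astype(float)
    values = table.drop(index=CELL_ROW).astype(float)
    neg = values.values < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"{path}: negative value at feature {values.index[i]!r}, "
            f"sample {values.columns[j]!r}"
        )
    return FeatureMatrix(values=values, cell_counts=cells)
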