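"""Descriptor-matrix container and post-processing.

A descriptor matrix is a plain numeric table: one row per molecule, one
named column per 2D descriptor (~700 columns in a typical Mold2 run), plus
an optional binary drug-likeness label per row.  Post-processing consists
of two row/column filters applied after descriptor calculation —

* any row containing a missing or non-finite descriptor value is removed
  (descriptor programs emit ``N/A``/``infinity`` tokens for molecules they
  cannot handle);
* any descriptor column with the same value across all molecules carries
  no information and is removed —

followed by per-column z-score standardisation.  Standardisation
statistics are always fit on the training rows only and then applied to
held-out rows, so that validation data never leaks into the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DataError

#: Tokens recognised as missing values in delimited input.
NA_TOKENS = ["NA", "N/A", "NaN", "nan", ""]


@dataclass
class DescriptorMatrix:
    """Named numeric feature table with row identifiers and optional labels.

    Parameters
    ----------
    values
        Float matrix of shape ``(n_rows, n_cols)``.
    row_ids
        One identifier per row (molecule ids).
    col_names
        One name per column (descriptor names).
    labels
        Optional per-row class label, 1 = drug-like/positive, 0 = negative.
    """

    values: np.ndarray
    row_ids: np.ndarray
    col_names: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("descriptor matrix must be 2-dimensional")
        self.row_ids = np.asarray(self.row_ids, dtype=object)
        self.col_names = np.asarray(self.col_names, dtype=object)
        if len(self.row_ids) != self.values.shape[0]:
            raise DataError("row_ids length does not match row count")
        if len(self.col_names) != self.values.shape[1]:
            raise DataError("col_names length does not match column count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != self.values.shape[0]:
                raise DataError("labels length does not match row count")
            if not np.isin(self.labels, [0, 1]).all():
                raise DataError("labels must be binary (0/1)")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def select_rows(self, index: np.ndarray) -> "DescriptorMatrix":
        """Return a copy restricted to the given row positions (order kept)."""
        index = np.asarray(index)
        return DescriptorMatrix(
            values=self.values[index].copy(),
            row_ids=self.row_ids[index].copy(),
            col_names=self.col_names.copy(),
            labels=None if self.labels is None else self.labels[index].copy(),
        )

    def select_cols(self, mask: np.ndarray) -> "DescriptorMatrix":
        """Return a copy restricted to the columns where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return DescriptorMatrix(
            values=self.values[:, mask].copy(),
            row_ids=self.row_ids.copy(),
            col_names=self.col_names[mask].copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def to_frame(self, include_labels: bool = True) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.col_names))
        frame.insert(0, "id", list(self.row_ids))
        if include_labels and self.labels is not None:
            frame["label"] = self.labels
        return frame

    def to_csv(self, path: str | Path, include_labels: bool = True) -> None:
        self.to_frame(include_labels=include_labels).to_csv(path, index=False)


def read_matrix(
    path: str | Path,
    labels_path: str | Path | None = None,
    label_col: str = "label",
    sep: str | None = None,
) -> DescriptorMatrix:
    """Read a delimited descriptor table.

    The first column is taken as the molecule id and the header row as
    descriptor names.  Labels may live in a ``label`` column of the matrix
    file or in a separate two-column ``id,label`` file.  The tokens listed
    in :data:`NA_TOKENS` and ``±inf`` are parsed as non-finite values and
    survive into the matrix, to be handled by :func:`drop_error_rows`.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"matrix file not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, na_values=NA_TOKENS, keep_default_na=True)
    if frame.shape[1] < 2:
        raise DataError(f"matrix file {path} has fewer than two columns")
    id_col = frame.columns[0]
    row_ids = frame[id_col].astype(str).to_numpy(dtype=object)
    frame = frame.drop(columns=[id_col])

    labels = None
    if label_col in frame.columns:
        labels = frame[label_col].to_numpy()
        frame = frame.drop(columns=[label_col])
    if labels_path is not None:
        lab = pd.read_csv(labels_path)
        if lab.shape[1] < 2:
            raise DataError(f"label file {labels_path} must have id,label columns")
        mapping = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1]))
        try:
            labels = np.array([mapping[r] for r in row_ids])
        except KeyError as exc:
            raise DataError(f"label file missing id {exc.args[0]!r}") from exc

    # 'infinity'/'inf' tokens become object columns; coerce them to floats
    values = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return DescriptorMatrix(values, row_ids, frame.columns.to_numpy(dtype=object), labels)


def drop_error_rows(m: DescriptorMatrix) -> tuple[DescriptorMatrix, list]:
    """Remove every molecule (row) containing any missing or non-finite value.

    Returns the filtered matrix and the ids of the removed rows.  The
    column set is unchanged.  Removing all rows is fatal.
    """
    bad = ~np.isfinite(m.values).all(axis=1)
    if bad.all():
        raise DataError("all rows contain missing/non-finite values")
    kept = m.select_rows(np.flatnonzero(~bad))
    return kept, list(m.row_ids[bad])


def drop_constant_columns(m: DescriptorMatrix) -> tuple[DescriptorMatrix, list]:
    """Remove every descriptor (column) with the same value across all rows.

    Constancy means exact equality of all entries.  The row set is
    unchanged.  Removing all columns is fatal.
    """
    if m.n_rows == 0:
        raise DataError("cannot detect constant columns in an empty matrix")
    constant = (m.values == m.values[0]).all(axis=0)
    if constant.all():
        raise DataError("all columns are constant")
    kept = m.select_cols(~constant)
    return kept, list(m.col_names[constant])


@dataclass
class ColumnStats:
    """Per-column mean and population standard deviation from a fit subset."""

    col_names: np.ndarray
    mean: np.ndarray
    sd: np.ndarray


class ZScoreScaler(BaseEstimator, TransformerMixin):
    """Per-column z-score standardiser using the population convention.

    ``transform`` maps each column to ``(x - mean) / sd`` with statistics
    estimated (``sd`` with the 1/n convention) on the rows passed to
    :meth:`fit` — always the training rows, never held-out ones.  Columns
    that are constant on the fit rows are an error: they must be removed
    by :func:`drop_constant_columns` first.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DataError("ZScoreScaler expects a 2-D array")
        if X.shape[0] < 2:
            raise DataError("z-score statistics need at least two fit rows")
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)  # population (ddof=0)
        zero = self.sd_ == 0
        if zero.any():
            raise DataError(
                f"zero standard deviation on fit rows for columns {np.flatnonzero(zero).tolist()}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        self._check_cols(X)
        return (X - self.mean_) / self.sd_

    def inverse_transform(self, X):
        X = np.asarray(X, dtype=float)
        self._check_cols(X)
        return X * self.sd_ + self.mean_

    def _check_cols(self, X) -> None:
        if not hasattr(self, "mean_"):
            raise DataError("ZScoreScaler is not fitted")
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"column mismatch: scaler fitted on {self.n_features_in_} columns, got {X.shape[1]}"
            )


def zscore_fit(m: DescriptorMatrix, fit_rows: Sequence[int] | np.ndarray) -> ColumnStats:
    """Compute per-column mean/sd on a designated row subset only."""
    fit_rows = np.asarray(fit_rows)
    scaler = ZScoreScaler().fit(m.values[fit_rows])
    return ColumnStats(m.col_names.copy(), scaler.mean_, scaler.sd_)


def zscore_apply(m: DescriptorMatrix, stats: ColumnStats) -> DescriptorMatrix:
    """Standardise any row set of ``m`` with previously fitted statistics."""
    if len(stats.col_names) != m.n_cols or not (stats.col_names == m.col_names).all():
        raise DataError("column names of matrix and statistics do not match")
    return DescriptorMatrix(
        (m.values - stats.mean) / stats.sd,
        m.row_ids.copy(),
        m.col_names.copy(),
        None if m.labels is None else m.labels.copy(),
    )


def postprocess(m: DescriptorMatrix) -> tuple[DescriptorMatrix, dict]:
    """Apply both post-processing filters: error rows, then constant columns."""
    m1, removed_rows = drop_error_rows(m)
    m2, removed_cols = drop_constant_columns(m1)
    return m2, {"removed_row_ids": removed_rows, "removed_col_names": removed_cols}
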