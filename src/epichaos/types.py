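"""Core domain types shared across the package.

The central object is :class:`BinaryMatrix`, a features-by-cells 0/1
indicator matrix stored sparsely, together with feature identifiers and
cell barcodes.  Feature coordinates travel separately as a pandas
DataFrame with ``chrom``/``start``/``end`` columns (BED convention,
0-based half-open), one row per matrix feature in matrix order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "EpichaosError",
    "InputError",
    "EpichaosWarning",
    "DegenerateRunWarning",
    "BinaryMatrix",
    "PairSimilarity",
    "Replicate",
    "RegionSet",
    "validate_feature_table",
    "validate_grouping",
]


class EpichaosError(ValueError):
    """Base class for user-facing errors."""


class InputError(EpichaosError):
    """Invalid or inconsistent input data."""


class EpichaosWarning(UserWarning):
    """Base class for package warnings."""


class DegenerateRunWarning(EpichaosWarning):
    """A run hit a documented degenerate case (e.g. all scores equal)."""


def _as_str_array(ids: Iterable[str], what: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.ndim != 1:
        raise InputError(f"{what} must be one-dimensional")
    return arr


@dataclass
class BinaryMatrix:
    """Features x cells presence/absence matrix (sparse contract).

    Parameters
    ----------
    values
        ``scipy.sparse.csr_matrix`` of shape (n_features, n_cells) whose
        stored entries are all 1 (uint8).
    feature_ids, cell_ids
        Ordered unique string identifiers for rows and columns.
    """

    values: sp.csr_matrix
    feature_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            raise InputError("values must be a scipy sparse matrix; use from_dense()")
        self.values = sp.csr_matrix(self.values, dtype=np.uint8)
        self.values.eliminate_zeros()
        if self.values.nnz and not np.all(self.values.data == 1):
            raise InputError("matrix entries must be 0 or 1; call binarize() first")
        self.feature_ids = _as_str_array(self.feature_ids, "feature_ids")
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        nf, nc = self.values.shape
        if len(self.feature_ids) != nf:
            raise InputError(
                f"feature_ids length {len(self.feature_ids)} != matrix rows {nf}"
            )
        if len(self.cell_ids) != nc:
            raise InputError(f"cell_ids length {len(self.cell_ids)} != matrix cols {nc}")
        for name, ids in (("feature_ids", self.feature_ids), ("cell_ids", self.cell_ids)):
            if len(set(ids)) != len(ids):
                seen: set = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise InputError(f"duplicate {name[:-1]}: {dup!r}")
        self._cell_index: dict | None = None

    # -- constructors ------------------------------------------------
    @classmethod
    def from_dense(
        cls,
        arr: np.ndarray,
        feature_ids: Sequence[str] | None = None,
        cell_ids: Sequence[str] | None = None,
    ) -> "BinaryMatrix":
        arr = np.asarray(arr)
        if arr.ndim != 2:
            raise InputError("dense matrix must be 2-D (features x cells)")
        nf, nc = arr.shape
        if feature_ids is None:
            feature_ids = [f"f{i}" for i in range(nf)]
        if cell_ids is None:
            cell_ids = [f"c{j}" for j in range(nc)]
        return cls(sp.csr_matrix(arr, dtype=np.uint8), np.asarray(feature_ids, dtype=object), np.asarray(cell_ids, dtype=object))

    # -- accessors ---------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return self.values.toarray()

    def cell_indices(self, cell_ids: Sequence[str]) -> np.ndarray:
        """Column indices for the given barcodes (error on unknown ids)."""
        if self._cell_index is None:
            self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([self._cell_index[c] for c in cell_ids], dtype=np.intp)
        except KeyError as exc:
            raise InputError(f"cell id not present in matrix: {exc.args[0]!r}") from None

    def dense_columns(self, idx: np.ndarray) -> np.ndarray:
        """Dense uint8 block of the selected columns (features x k)."""
        return self.values[:, idx].toarray()

    def col_sums(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel().astype(np.int64)

    def subset_rows(self, idx: np.ndarray) -> "BinaryMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return BinaryMatrix(
            sp.csr_matrix(self.values[idx, :]), self.feature_ids[idx], self.cell_ids
        )

    def subset_cols(self, idx: np.ndarray) -> "BinaryMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return BinaryMatrix(
            sp.csr_matrix(self.values[:, idx]), self.feature_ids, self.cell_ids[idx]
        )


@dataclass(frozen=True)
class PairSimilarity:
    """Chance-centered Jaccard similarity of one cell pair."""

    cell_i: str
    cell_j: str
    observed: float  # Jaccard index J in [0, 1]
    expected: float  # independence expectation E in [0, 1)
    centered: float  # J - E in (-1, 1]


@dataclass(frozen=True)
class Replicate:
    """One scoring unit: a (group, replicate index, member cells) triple."""

    group: str
    replicate: int
    cell_ids: tuple


@dataclass
class RegionSet:
    """A named collection of genomic intervals (0-based half-open)."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end"]).copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            row = df.loc[bad[0]]
            raise InputError(
                f"region set {self.name!r}: invalid interval "
                f"{row['chrom']}:{row['start']}-{row['end']} (start must be < end)"
            )
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)


def validate_feature_table(features: pd.DataFrame, n_features: int) -> pd.DataFrame:
    """Check a chrom/start/end table aligned to matrix rows."""
    for col in ("chrom", "start", "end"):
        if col not in features.columns:
            raise InputError(f"feature table missing column {col!r}")
    if len(features) != n_features:
        raise InputError(
            f"feature table has {len(features)} rows but matrix has {n_features} features"
        )
    features = features.reset_index(drop=True)
    if (features["start"] >= features["end"]).any():
        i = int((features["start"] >= features["end"]).idxmax())
        raise InputError(f"feature row {i}: start >= end")
    return features


def validate_grouping(grouping: Mapping[str, str], m: BinaryMatrix) -> None:
    """Every grouped cell must exist in the matrix."""
    m.cell_indices(list(grouping))
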