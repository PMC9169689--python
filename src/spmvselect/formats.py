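"""Sparse matrix storage layouts and their SpMV kernels.

The central operation of a rate-coded neural network step is the weighted
sum of pre-synaptic firing rates, ``y = W @ x``: a sparse matrix-vector
multiplication (SpMV) between the synaptic weight matrix ``W`` (rows index
post-synaptic neurons, columns pre-synaptic neurons) and the dense rate
vector ``x``.  How ``W`` is laid out in memory dominates the cost of that
product, so this module implements the four layouts the selector chooses
among:

* :class:`CSRMatrix` — compressed sparse row (Yale): a row-pointer array
  plus packed column-index and value arrays.
* :class:`ELLPACKMatrix` — nonzeros packed into two ``n_rows x maxnzr``
  dense matrices (column indices and values); short rows are padded with a
  sentinel column index of ``-1`` and a value of ``0.0``.
* :class:`ELLPACKRMatrix` — ELLPACK plus an explicit per-row length array
  ``rl``, letting the kernel skip the per-cell sentinel test.
* :class:`DenseMatrix` — a plain 2-d array with absent connections stored
  as ``0.0``.

All layouts are lossless views of a :class:`ConnectivityMatrix`, the
canonical coordinate-list representation, and all SpMV kernels agree with
the brute-force dense product to double-precision accuracy.  Column indices
are kept sorted ascending within each row so every conversion is
deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import scipy.io
import scipy.sparse

__all__ = [
    "Layout",
    "ConnectivityMatrix",
    "CSRMatrix",
    "ELLPACKMatrix",
    "ELLPACKRMatrix",
    "DenseMatrix",
    "FormatMatrix",
    "to_csr",
    "to_ellpack",
    "to_ellpack_r",
    "to_dense",
    "spmv",
    "read_matrix_market",
    "write_matrix_market",
]

#: Sentinel column index marking padded (absent) cells in ELLPACK layouts.
PAD_SENTINEL = -1


class Layout(str, enum.Enum):
    """Memory order of the two ELLPACK dense matrices.

    ``ROW_MAJOR`` is cache-friendly for a sequential CPU kernel that walks
    one row at a time; ``COLUMN_MAJOR`` is the GPU-friendly order in which
    adjacent threads (one per row) read adjacent addresses.  The two are
    value-equivalent here — only the underlying stride changes.
    """

    ROW_MAJOR = "row-major"
    COLUMN_MAJOR = "column-major"


def _as_order(a: np.ndarray, layout: Layout) -> np.ndarray:
    if layout is Layout.COLUMN_MAJOR:
        return np.asfortranarray(a)
    return np.ascontiguousarray(a)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Coordinate-list representation of a synaptic weight matrix.

    Rows index post-synaptic neurons (``N`` of them), columns pre-synaptic
    neurons (``M``).  Entries are stored canonically sorted by ``(row,
    col)`` with no duplicate coordinates; rows with no entries are legal.
    """

    n_rows: int
    n_cols: int
    rows: np.ndarray = field(repr=False)
    cols: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("matrix dimensions must be positive")
        rows = np.asarray(self.rows, dtype=np.int64)
        cols = np.asarray(self.cols, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        if not (rows.shape == cols.shape == values.shape) or rows.ndim != 1:
            raise ValueError("rows, cols and values must be 1-d arrays of equal length")
        if rows.size:
            if rows.min() < 0 or rows.max() >= self.n_rows:
                raise ValueError("row index out of range")
            if cols.min() < 0 or cols.max() >= self.n_cols:
                raise ValueError("column index out of range")
        # canonical (row, col) order; duplicates become adjacent and detectable
        order = np.lexsort((cols, rows))
        rows, cols, values = rows[order], cols[order], values[order]
        if rows.size > 1:
            same = (np.diff(rows) == 0) & (np.diff(cols) == 0)
            if same.any():
                i = int(np.flatnonzero(same)[0])
                raise ValueError(
                    f"duplicate coordinate ({rows[i]}, {cols[i]}) in entry list"
                )
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "cols", cols)
        object.__setattr__(self, "values", values)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_entries(
        cls,
        n_rows: int,
        n_cols: int,
        entries: Iterable[tuple[int, int, float]],
    ) -> "ConnectivityMatrix":
        """Build from an iterable of ``(row, col, value)`` triples."""
        triples = list(entries)
        if triples:
            r, c, v = map(np.asarray, zip(*triples))
        else:
            r = c = v = np.empty(0)
        return cls(n_rows, n_cols, r, c, v)

    @classmethod
    def from_dense(cls, a: np.ndarray) -> "ConnectivityMatrix":
        """Build from a 2-d array; exact zeros are treated as absent."""
        a = np.asarray(a, dtype=np.float64)
        if a.ndim != 2:
            raise ValueError("expected a 2-d array")
        r, c = np.nonzero(a)
        return cls(a.shape[0], a.shape[1], r, c, a[r, c])

    # -- basic queries ------------------------------------------------
    @property
    def nnz(self) -> int:
        return int(self.rows.size)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def row_lengths(self) -> np.ndarray:
        """Number of stored entries per row (length ``n_rows``)."""
        return np.bincount(self.rows, minlength=self.n_rows).astype(np.int64)

    def to_dense(self) -> np.ndarray:
        a = np.zeros(self.shape)
        a[self.rows, self.cols] = self.values
        return a

    def to_coo(self) -> scipy.sparse.coo_array:
        return scipy.sparse.coo_array(
            (self.values, (self.rows, self.cols)), shape=self.shape
        )


def _check_x(n_cols: int, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size != n_cols:
        raise ValueError(f"input vector must have length {n_cols}, got shape {x.shape}")
    return x


@dataclass(frozen=True)
class CSRMatrix:
    """Compressed sparse row layout: ``row_ptr``, ``col_idx``, ``values``."""

    n_rows: int
    n_cols: int
    row_ptr: np.ndarray = field(repr=False)
    col_idx: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    @property
    def nnz(self) -> int:
        return int(self.col_idx.size)

    def spmv(self, x: np.ndarray) -> np.ndarray:
        """Row-wise kernel: ``y[i] = sum(values[s:e] * x[col_idx[s:e]])``.

        Implemented as segmented sums over the packed product array;
        empty rows contribute exact zeros.
        """
        x = _check_x(self.n_cols, x)
        y = np.zeros(self.n_rows)
        if self.nnz == 0:
            return y
        prod = self.values * x[self.col_idx]
        starts = np.flatnonzero(np.diff(self.row_ptr))  # rows with entries
        y[starts] = np.add.reduceat(prod, self.row_ptr[starts])
        return y

    def toarray(self) -> np.ndarray:
        a = np.zeros((self.n_rows, self.n_cols))
        rows = np.repeat(np.arange(self.n_rows), np.diff(self.row_ptr))
        a[rows, self.col_idx] = self.values
        return a


@dataclass(frozen=True)
class ELLPACKMatrix:
    """ELLPACK/ITPACK layout: two ``n_rows x maxnzr`` dense matrices.

    Padded cells carry the sentinel ``-1`` in ``col_idx`` and ``0.0`` in
    ``values``; within each row all valid entries precede the padding.
    """

    n_rows: int
    n_cols: int
    maxnzr: int
    col_idx: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    layout: Layout = Layout.ROW_MAJOR

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.col_idx >= 0))

    def spmv(self, x: np.ndarray) -> np.ndarray:
        """Kernel with the per-cell sentinel test (`col_idx >= 0`)."""
        x = _check_x(self.n_cols, x)
        if self.maxnzr == 0:
            return np.zeros(self.n_rows)
        valid = self.col_idx >= 0  # the sentinel check this format requires
        gathered = np.where(valid, x[np.where(valid, self.col_idx, 0)], 0.0)
        return (self.values * gathered).sum(axis=1)

    def toarray(self) -> np.ndarray:
        a = np.zeros((self.n_rows, self.n_cols))
        r, k = np.nonzero(self.col_idx >= 0)
        a[r, self.col_idx[r, k]] = self.values[r, k]
        return a


@dataclass(frozen=True)
class ELLPACKRMatrix(ELLPACKMatrix):
    """ELLPACK-R: ELLPACK plus the per-row length array ``rl``."""

    rl: np.ndarray = field(default=None, repr=False)  # set in conversion

    def spmv(self, x: np.ndarray) -> np.ndarray:
        """Kernel driven by ``rl`` only — no sentinel comparison."""
        x = _check_x(self.n_cols, x)
        if self.maxnzr == 0:
            return np.zeros(self.n_rows)
        within = np.arange(self.maxnzr)[None, :] < self.rl[:, None]
        gathered = x[np.where(within, self.col_idx, 0)]
        return (self.values * np.where(within, gathered, 0.0)).sum(axis=1)


@dataclass(frozen=True)
class DenseMatrix:
    """Plain 2-d layout; absent connections are stored ``0.0``."""

    n_rows: int
    n_cols: int
    values: np.ndarray = field(repr=False)

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.values))

    def spmv(self, x: np.ndarray) -> np.ndarray:
        x = _check_x(self.n_cols, x)
        return self.values @ x

    def toarray(self) -> np.ndarray:
        return np.array(self.values)


FormatMatrix = Union[CSRMatrix, ELLPACKMatrix, ELLPACKRMatrix, DenseMatrix]


# ---------------------------------------------------------------------
# conversions (all start from the canonical, duplicate-free coordinate list)
# ---------------------------------------------------------------------

def to_csr(m: ConnectivityMatrix) -> CSRMatrix:
    """Convert to compressed sparse row; columns sorted within each row."""
    row_ptr = np.zeros(m.n_rows + 1, dtype=np.int64)
    np.cumsum(m.row_lengths(), out=row_ptr[1:])
    # entries are already in (row, col) order
    return CSRMatrix(m.n_rows, m.n_cols, row_ptr, m.cols.copy(), m.values.copy())


def _ellpack_arrays(m: ConnectivityMatrix) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    rl = m.row_lengths()
    maxnzr = int(rl.max()) if m.n_rows else 0
    col_idx = np.full((m.n_rows, maxnzr), PAD_SENTINEL, dtype=np.int64)
    values = np.zeros((m.n_rows, maxnzr))
    if m.nnz:
        # position of each entry within its row (entries sorted by row, col)
        row_ptr = np.zeros(m.n_rows + 1, dtype=np.int64)
        np.cumsum(rl, out=row_ptr[1:])
        k = np.arange(m.nnz) - row_ptr[m.rows]
        col_idx[m.rows, k] = m.cols
        values[m.rows, k] = m.values
    return maxnzr, col_idx, values, rl


def to_ellpack(m: ConnectivityMatrix, layout: Layout = Layout.ROW_MAJOR) -> ELLPACKMatrix:
    maxnzr, col_idx, values, _ = _ellpack_arrays(m)
    return ELLPACKMatrix(
        m.n_rows, m.n_cols, maxnzr,
        _as_order(col_idx, layout), _as_order(values, layout), layout,
    )


def to_ellpack_r(m: ConnectivityMatrix, layout: Layout = Layout.ROW_MAJOR) -> ELLPACKRMatrix:
    maxnzr, col_idx, values, rl = _ellpack_arrays(m)
    return ELLPACKRMatrix(
        m.n_rows, m.n_cols, maxnzr,
        _as_order(col_idx, layout), _as_order(values, layout), layout, rl,
    )


def to_dense(m: ConnectivityMatrix) -> DenseMatrix:
    return DenseMatrix(m.n_rows, m.n_cols, m.to_dense())


_CONVERTERS = {
    "csr": to_csr,
    "ellpack": to_ellpack,
    "ellpack_r": to_ellpack_r,
    "dense": to_dense,
}


def convert(m: ConnectivityMatrix, format_name: str, **kwargs) -> FormatMatrix:
    """Convert by format name (one of ``csr``, ``ellpack``, ``ellpack_r``, ``dense``)."""
    try:
        conv = _CONVERTERS[format_name]
    except KeyError:
        raise ValueError(f"unknown format name: {format_name!r}") from None
    return conv(m, **kwargs)


def spmv(m: FormatMatrix, x: np.ndarray) -> np.ndarray:
    """The weighted sum ``y = W @ x`` under whichever layout ``m`` uses."""
    return m.spmv(x)


# ---------------------------------------------------------------------
# Matrix Market I/O (1-based on disk per the standard, 0-based in memory)
# ---------------------------------------------------------------------

def read_matrix_market(path: Union[str, Path]) -> ConnectivityMatrix:
    """Read a coordinate-format ``.mtx`` file into a ConnectivityMatrix."""
    a = scipy.io.mmread(str(path))
    coo = scipy.sparse.coo_array(a)
    return ConnectivityMatrix(
        coo.shape[0], coo.shape[1], coo.row, coo.col, coo.data
    )


def write_matrix_market(path: Union[str, Path], m: ConnectivityMatrix,
                        comment: str = "") -> None:
    """Write as Matrix Market coordinate format (real, general)."""
    scipy.io.mmwrite(str(path), m.to_coo(), comment=comment)
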