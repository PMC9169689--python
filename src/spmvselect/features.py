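"""The seven-descriptor feature vector characterizing a connectivity matrix.

The selector never looks at the matrix itself, only at seven cheap summary
statistics: the dimensions N and M, the nonzero count NNZ, the density
DES = NNZ/(N*M), and the mean/min/max number of nonzeros per row (AVGNZR,
MINNZR, MAXNZR).  Rows with no entries count toward AVGNZR's denominator
and can drive MINNZR to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import singledispatch

import numpy as np

from .formats import (
    ConnectivityMatrix,
    CSRMatrix,
    DenseMatrix,
    ELLPACKMatrix,
    ELLPACKRMatrix,
)

__all__ = ["FeatureVector", "extract_features", "FEATURE_NAMES"]

#: Fixed column order used in CSV serialization and as model input order.
FEATURE_NAMES = ("n", "m", "nnz", "des", "avgnzr", "minnzr", "maxnzr")


@dataclass(frozen=True)
class FeatureVector:
    n: int
    m: int
    nnz: int
    des: float
    avgnzr: float
    minnzr: int
    maxnzr: int

    def as_array(self) -> np.ndarray:
        """The seven features in :data:`FEATURE_NAMES` order."""
        return np.array(
            [self.n, self.m, self.nnz, self.des, self.avgnzr,
             self.minnzr, self.maxnzr],
            dtype=np.float64,
        )

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("feature vector requires positive dimensions")
        if not self.minnzr <= self.avgnzr <= self.maxnzr:
            raise ValueError("row-length statistics out of order")


def _from_row_lengths(n: int, m: int, rl: np.ndarray) -> FeatureVector:
    nnz = int(rl.sum())
    return FeatureVector(
        n=n,
        m=m,
        nnz=nnz,
        des=nnz / (n * m),
        avgnzr=nnz / n,
        minnzr=int(rl.min()),
        maxnzr=int(rl.max()),
    )


@singledispatch
def extract_features(m) -> FeatureVector:
    """Compute the seven descriptors; identical for every storage layout."""
    raise TypeError(f"cannot extract features from {type(m).__name__}")


@extract_features.register
def _(m: ConnectivityMatrix) -> FeatureVector:
    return _from_row_lengths(m.n_rows, m.n_cols, m.row_lengths())


@extract_features.register
def _(m: CSRMatrix) -> FeatureVector:
    return _from_row_lengths(m.n_rows, m.n_cols, np.diff(m.row_ptr))


@extract_features.register
def _(m: ELLPACKMatrix) -> FeatureVector:  # also covers ELLPACK-R subclass
    if isinstance(m, ELLPACKRMatrix):
        rl = m.rl
    else:
        rl = (m.col_idx >= 0).sum(axis=1)
    return _from_row_lengths(m.n_rows, m.n_cols, np.asarray(rl))


@extract_features.register
def _(m: DenseMatrix) -> FeatureVector:
    return _from_row_lengths(
        m.n_rows, m.n_cols, np.count_nonzero(m.values, axis=1)
    )
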