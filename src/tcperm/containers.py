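"""Core data containers: read-depth matrices, sample orderings, difference operators.

A read-depth matrix holds normalized copy-number signal for ``m`` samples
(cells) over ``n`` genomic bins, centered so that the normal two-copy state
maps to 0.  A sample ordering is a permutation of the samples, used both as
the unknown arrangement estimated by the solver and as the ground-truth
shuffle applied by the synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.fft import fft, ifft

from .errors import InvalidInputError

__all__ = ["ReadDepthMatrix", "SampleOrdering", "DifferenceOperator"]


def _as_float_matrix(values, name: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise InvalidInputError(f"{name} must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite entries")
    return arr


@dataclass
class ReadDepthMatrix:
    """An m-samples x n-bins matrix of zero-centered read-depth values.

    Parameters
    ----------
    values
        Real matrix, samples as rows.  Entry (i, j) is the normalized
        copy-number signal of sample i in bin j; 0 means two copies.
    sample_ids, bin_ids
        Unique identifiers for rows and columns.  Generated as
        ``s0, s1, ...`` / ``b0, b1, ...`` when omitted.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    bin_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _as_float_matrix(self.values)
        m, n = self.values.shape
        if m < 2:
            raise InvalidInputError(f"need at least 2 samples, got {m}")
        if n < 1:
            raise InvalidInputError("need at least 1 bin")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(m)]
        if not self.bin_ids:
            self.bin_ids = [f"b{j}" for j in range(n)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.bin_ids = [str(b) for b in self.bin_ids]
        if len(self.sample_ids) != m:
            raise InvalidInputError(
                f"{len(self.sample_ids)} sample_ids for {m} rows"
            )
        if len(self.bin_ids) != n:
            raise InvalidInputError(f"{len(self.bin_ids)} bin_ids for {n} columns")
        if len(set(self.sample_ids)) != m:
            raise InvalidInputError("sample_ids are not unique")
        if len(set(self.bin_ids)) != n:
            raise InvalidInputError("bin_ids are not unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def reorder(self, ordering: "SampleOrdering") -> "ReadDepthMatrix":
        """Rows rearranged so position k holds sample ``ordering.order[k]``."""
        idx = ordering.order
        return ReadDepthMatrix(
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            list(self.bin_ids),
        )

    def select_bins(self, indices: Sequence[int]) -> "ReadDepthMatrix":
        idx = np.asarray(indices, dtype=int)
        return ReadDepthMatrix(
            self.values[:, idx],
            list(self.sample_ids),
            [self.bin_ids[j] for j in idx],
        )


@dataclass
class SampleOrdering:
    """A permutation of sample indices: ``order[k]`` = source sample at position k.

    Interchangeable with its m x m binary permutation-matrix form P, defined
    so that ``P @ X_display`` puts each row back at its source index
    (equivalently ``P.T @ B == B[order]`` lays B out in display order).
    """

    order: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        m = self.order.size
        if self.order.ndim != 1 or m == 0:
            raise InvalidInputError("order must be a non-empty 1-D index sequence")
        if not np.array_equal(np.sort(self.order), np.arange(m)):
            raise InvalidInputError("order is not a bijection on 0..m-1")

    @classmethod
    def identity(cls, m: int) -> "SampleOrdering":
        return cls(np.arange(m))

    @property
    def size(self) -> int:
        return self.order.size

    @property
    def inverse(self) -> "SampleOrdering":
        return SampleOrdering(np.argsort(self.order))

    def matrix_form(self) -> np.ndarray:
        """The permutation matrix P with ``P[i, k] = 1`` iff ``order[k] == i``."""
        m = self.size
        P = np.zeros((m, m))
        P[self.order, np.arange(m)] = 1.0
        return P

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Rows of ``values`` rearranged into display order (== P.T @ values)."""
        return np.asarray(values)[self.order]

    def compose(self, other: "SampleOrdering") -> "SampleOrdering":
        """Ordering equivalent to applying ``other`` first, then ``self``."""
        return SampleOrdering(other.order[self.order])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleOrdering):
            return NotImplemented
        return np.array_equal(self.order, other.order)


class DifferenceOperator:
    """First-order difference D along the sample axis.

    ``(D @ X)[i] = X[i] - X[i-1]``.  With a circular boundary the i = 0 row
    wraps to the last sample, making D circulant and therefore diagonalized
    by the DFT: ``D = F^-1 diag(K) F`` with ``K`` the DFT of D's first
    column.  With an open boundary the first row is zero, so split variables
    keep the full m x n shape.
    """

    def __init__(self, size: int, boundary: str = "circular") -> None:
        if size < 2:
            raise InvalidInputError(f"difference operator needs m >= 2, got {size}")
        if boundary not in ("circular", "open"):
            raise InvalidInputError(f"unknown boundary {boundary!r}")
        self.size = int(size)
        self.boundary = boundary
        if boundary == "circular":
            first_col = np.zeros(size)
            first_col[0] = 1.0
            first_col[1] = -1.0
            self.spectrum: np.ndarray | None = fft(first_col)
        else:
            self.spectrum = None

    @property
    def matrix_form(self) -> np.ndarray:
        m = self.size
        D = np.eye(m) - np.eye(m, k=-1)
        if self.boundary == "circular":
            D[0, m - 1] = -1.0
        else:
            D[0, 0] = 0.0
        return D

    def apply(self, X: np.ndarray) -> np.ndarray:
        """D @ X without forming the matrix."""
        X = np.asarray(X, dtype=float)
        out = X - np.roll(X, 1, axis=0)
        if self.boundary == "open":
            out[0] = 0.0
        return out

    def apply_transpose(self, X: np.ndarray) -> np.ndarray:
        """D.T @ X without forming the matrix."""
        X = np.asarray(X, dtype=float)
        if self.boundary == "circular":
            return X - np.roll(X, -1, axis=0)
        Xz = X.copy()
        Xz[0] = 0.0
        out = Xz - np.roll(Xz, -1, axis=0)
        out[-1] = Xz[-1]
        return out

    def reconstruct_from_spectrum(self) -> np.ndarray:
        """Dense D rebuilt as F^-1 diag(K) F; circular boundary only."""
        if self.spectrum is None:
            raise InvalidInputError("spectrum is defined only for circular boundary")
        m = self.size
        return np.real(ifft(self.spectrum[:, None] * fft(np.eye(m), axis=0), axis=0))
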