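"""Laplacian-Score feature selection.

Scores each bin by how well it preserves locality on a k-nearest-neighbor
sample graph: relevant copy-number bins vary between sample subpopulations
but are near-constant within a neighborhood, while irrelevant bins are
noise everywhere.  Lower score = more locality-preserving = more relevant.

For a heat-kernel weight matrix ``S_ij = exp(-d_ij^2 / t)`` over the kNN
graph, with degree matrix ``Deg`` and graph Laplacian ``L = Deg - S``, the
score of a feature column f is ``(f~' L f~) / (f~' Deg f~)`` where f~ is f
centered by its degree-weighted mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .containers import ReadDepthMatrix
from .errors import InvalidInputError

__all__ = ["LaplacianScoreResult", "laplacian_score", "select_features"]


@dataclass
class LaplacianScoreResult:
    scores: np.ndarray
    neighbor_count: int
    bandwidth: float
    kept_indices: np.ndarray | None = None


def laplacian_score(
    B: ReadDepthMatrix | np.ndarray,
    k_neighbors: int = 5,
    bandwidth: float | str = "auto",
) -> LaplacianScoreResult:
    """Laplacian Score of every bin of B.

    The sample graph connects each sample to its ``k_neighbors`` nearest
    neighbors under Euclidean distance (symmetrized: i ~ j if either is a
    neighbor of the other).  ``bandwidth="auto"`` uses the mean squared
    kNN distance as the heat-kernel scale t.  Zero-variance features get a
    +inf sentinel (maximally irrelevant).
    """
    values = B.values if isinstance(B, ReadDepthMatrix) else np.asarray(B, dtype=float)
    m, n = values.shape
    if not 1 <= k_neighbors < m:
        raise InvalidInputError(
            f"need 1 <= k_neighbors < n_samples, got k={k_neighbors}, m={m}"
        )

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(values)
    dist, idx = nn.kneighbors(values)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self-neighbors

    if bandwidth == "auto":
        t = float(np.mean(dist**2))
        if t == 0.0:
            t = 1.0  # all samples identical; weights become uniform
    else:
        t = float(bandwidth)
        if t <= 0:
            raise InvalidInputError(f"bandwidth must be > 0, got {bandwidth}")

    S = np.zeros((m, m))
    rows = np.repeat(np.arange(m), k_neighbors)
    w = np.exp(-(dist.ravel() ** 2) / t)
    S[rows, idx.ravel()] = w
    S = np.maximum(S, S.T)  # symmetrize: edge if either side is a kNN

    deg = S.sum(axis=1)
    total_deg = deg.sum()
    scores = np.empty(n)
    for j in range(n):
        f = values[:, j]
        f_tilde = f - (f @ deg) / total_deg
        denom = f_tilde @ (deg * f_tilde)
        if denom <= 1e-12 * max(float(f @ f), 1.0):
            scores[j] = math.inf
            continue
        numer = f_tilde @ (deg * f_tilde) - f_tilde @ (S @ f_tilde)  # f~' L f~
        scores[j] = numer / denom
    return LaplacianScoreResult(scores=scores, neighbor_count=k_neighbors, bandwidth=t)


def select_features(
    B: ReadDepthMatrix | np.ndarray,
    result: LaplacianScoreResult,
    keep_fraction: float,
) -> ReadDepthMatrix:
    """Retain the ceil(keep_fraction * n) lowest-scoring bins.

    Original bin order is preserved; ties on equal scores are broken toward
    the lower bin index.  The kept indices are recorded on ``result``.
    """
    if not 0 < keep_fraction <= 1:
        raise InvalidInputError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if not isinstance(B, ReadDepthMatrix):
        B = ReadDepthMatrix(np.asarray(B, dtype=float))
    n = B.n_bins
    if result.scores.shape[0] != n:
        raise InvalidInputError("scores length does not match bin count")
    n_keep = math.ceil(keep_fraction * n)
    # stable argsort: equal scores resolve to the lower index
    ranked = np.argsort(result.scores, kind="stable")[:n_keep]
    kept = np.sort(ranked)
    result.kept_indices = kept
    return B.select_bins(kept)
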