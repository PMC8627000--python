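"""Bipartite-graph scoring: nearest profile (NP) and weighted profile (WP).

The NP step sparsifies a fused similarity matrix to each entity's single
most similar neighbour (self-similarity removed). The WP step then predicts
each entity's association profile as the similarity-weighted average of its
neighbours' profiles; with an NP-sparsified weight matrix this transfers the
nearest neighbour's profile. The miRNA-side and disease-side predictions are
averaged into the bipartite score matrix Y1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import SimilarityMatrix
from .errors import MatrixValidationError, ParameterError

__all__ = ["NearestNeighbourMatrix", "nearest_profile", "weighted_profile", "bipartite_scores"]


@dataclass(frozen=True)
class NearestNeighbourMatrix:
    """Row-sparse neighbour weights: at most one nonzero per row, zero diagonal."""

    values: np.ndarray
    labels: tuple[str, ...]
    kind: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise MatrixValidationError("nearest-neighbour matrix must be square")
        if (v < 0).any():
            raise MatrixValidationError("nearest-neighbour weights must be non-negative")
        if np.diag(v).any():
            raise MatrixValidationError("nearest-neighbour matrix must have zero diagonal")
        if (np.count_nonzero(v, axis=1) > 1).any():
            raise MatrixValidationError("each row may hold at most one neighbour weight")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))


def nearest_profile(K: SimilarityMatrix) -> NearestNeighbourMatrix:
    """Keep only each entity's single most similar other entity.

    The diagonal is zeroed first; per row the argmax off-diagonal similarity
    is retained (ties broken by lowest index). A zero argmax (e.g. identity
    input) leaves the row empty.
    """
    q = len(K.labels)
    W = K.values.copy()
    np.fill_diagonal(W, 0.0)
    N = np.zeros_like(W)
    if q == 1:
        warnings.warn("similarity matrix has a single entity; no neighbour exists")
        return NearestNeighbourMatrix(N, K.labels, K.kind)
    j_star = np.argmax(W, axis=1)  # np.argmax takes the first (lowest-index) maximum
    rows = np.arange(q)
    vals = W[rows, j_star]
    keep = vals > 0
    N[rows[keep], j_star[keep]] = vals[keep]
    return NearestNeighbourMatrix(N, K.labels, K.kind)


def weighted_profile(N: NearestNeighbourMatrix, Y: np.ndarray, axis: str) -> np.ndarray:
    """Similarity-weighted neighbour average of association profiles.

    For the miRNA axis, row i of the result is the weighted average of the
    other miRNAs' rows of Y; for the disease axis, column i is the weighted
    average of the other diseases' columns. Zero-weight rows/columns yield
    zeros.
    """
    Y = np.asarray(Y, dtype=float)
    W = N.values
    if axis == "miRNA":
        if W.shape[0] != Y.shape[0]:
            raise MatrixValidationError("miRNA neighbour matrix does not match Y rows")
        denom = W.sum(axis=1)
        out = np.zeros_like(Y)
        ok = denom > 0
        out[ok] = (W @ Y)[ok] / denom[ok, None]
        return out
    if axis == "disease":
        if W.shape[0] != Y.shape[1]:
            raise MatrixValidationError("disease neighbour matrix does not match Y columns")
        denom = W.sum(axis=1)
        out = np.zeros_like(Y)
        ok = denom > 0
        out[:, ok] = (Y @ W.T)[:, ok] / denom[ok]
        return out
    raise ParameterError(f"axis must be 'miRNA' or 'disease', got {axis!r}")


def bipartite_scores(Km: SimilarityMatrix, Kd: SimilarityMatrix, Y: np.ndarray) -> np.ndarray:
    """Bipartite score matrix Y1: average of miRNA-side and disease-side WP."""
    Nm = nearest_profile(Km)
    Nd = nearest_profile(Kd)
    wp_m = weighted_profile(Nm, Y, "miRNA")
    wp_d = weighted_profile(Nd, Y, "disease")
    return (wp_m + wp_d) / 2.0
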