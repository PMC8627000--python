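"""WKNKN pre-imputation of unknown association entries.

Many true associations are missing (recorded as 0) in a curated bipartite
matrix. WKNKN (weighted K nearest known neighbours) replaces unknown entries
with a decay-weighted average of the profiles of the K most similar miRNAs
(and, symmetrically, diseases) that have at least one known association,
then keeps the maximum of the original entry and the averaged estimate, so
known associations are never decreased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix, SimilarityMatrix
from .errors import LabelError, ParameterError

__all__ = ["WknknParams", "wknkn_impute"]


@dataclass(frozen=True)
class WknknParams:
    """K nearest known neighbours with per-rank decay p in (0, 1]."""

    K: int = 7
    p: float = 0.6

    def __post_init__(self):
        if self.K < 1:
            raise ParameterError(f"K must be >= 1, got {self.K}")
        if not 0 < self.p <= 1:
            raise ParameterError(f"p must be in (0, 1], got {self.p}")


def _neighbour_estimate(Y: np.ndarray, K_sim: np.ndarray, params: WknknParams) -> np.ndarray:
    """Row-wise decay-weighted neighbour average of Y using similarity K_sim."""
    n = Y.shape[0]
    known = Y.sum(axis=1) > 0
    est = np.zeros_like(Y, dtype=float)
    decay = params.p ** np.arange(params.K)
    short = 0
    for i in range(n):
        eligible = np.flatnonzero(known)
        eligible = eligible[eligible != i]
        if eligible.size == 0:
            continue
        sims = K_sim[i, eligible]
        order = np.argsort(-sims, kind="stable")  # ties resolved by input order
        take = order[: params.K]
        if take.size < params.K:
            short += 1
        w = decay[: take.size] * sims[take]
        wsum = w.sum()
        if wsum > 0:
            est[i] = w @ Y[eligible[take]] / wsum
    if short:
        warnings.warn(
            f"{short} profile(s) had fewer than K={params.K} known neighbours; used all available"
        )
    return est


def wknkn_impute(
    Y: AssociationMatrix,
    Km: SimilarityMatrix,
    Kd: SimilarityMatrix,
    params: WknknParams = WknknParams(),
) -> np.ndarray:
    """Impute unknown entries of Y from known nearest neighbours.

    Returns a real-valued matrix in [0, 1]: the elementwise maximum of Y and
    the average of the miRNA-side and disease-side neighbour estimates.
    """
    if Km.labels != Y.row_labels:
        raise LabelError("miRNA similarity labels must equal Y row labels")
    if Kd.labels != Y.col_labels:
        raise LabelError("disease similarity labels must equal Y column labels")
    Ym = _neighbour_estimate(Y.values, Km.values, params)
    Yd = _neighbour_estimate(Y.values.T, Kd.values, params).T
    out = np.maximum(Y.values, (Ym + Yd) / 2.0)
    return np.clip(out, 0.0, 1.0)
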