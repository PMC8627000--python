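"""Synthetic datasets with planted low-rank bipartite structure.

The generator emulates the statistical shape of a curated miRNA-disease
association dataset: a sparse binary matrix whose 1-entries are the largest
entries of a planted non-negative low-rank score matrix A* B*^T, plus
miRNA/disease similarity matrices derived from the cosine similarity of the
planted factors (so "similar entities associate with similar partners"
holds by construction), perturbed by symmetric noise. Everything is fully
determined by the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix, SimilarityMatrix
from .errors import ParameterError
from .similarity import DiseaseDAG

__all__ = ["SyntheticSpec", "generate_dataset", "generate_dags", "hmdd_shaped_spec", "shuffled_null"]


@dataclass(frozen=True)
class SyntheticSpec:
    n: int = 100
    m: int = 80
    rank: int = 5
    density: float = 0.05
    similarity_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.rank > min(self.n, self.m):
            raise ParameterError("rank must not exceed min(n, m)")
        if not 0 < self.density < 1:
            raise ParameterError("density must be in (0, 1)")
        if self.similarity_noise < 0:
            raise ParameterError("similarity_noise must be non-negative")


def hmdd_shaped_spec(seed: int = 0) -> SyntheticSpec:
    """Preset with the shape of HMDD v2.0: 495 x 383 with 5430 positives."""
    return SyntheticSpec(n=495, m=383, rank=10, density=5430 / (495 * 383), seed=seed)


def _cosine_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    norms[norms == 0] = 1.0
    Xn = X / norms[:, None]
    C = np.clip(Xn @ Xn.T, 0.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def _noisy_similarity(C: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    if noise > 0:
        E = rng.normal(0.0, noise, C.shape)
        C = C + (E + E.T) / 2.0
    C = np.clip(C, 0.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def generate_dataset(
    spec: SyntheticSpec = SyntheticSpec(),
) -> tuple[AssociationMatrix, SimilarityMatrix, SimilarityMatrix, dict]:
    """Draw a planted dataset; returns (Y, Sm, Sd, latent truth).

    Latent factors are gamma-distributed (non-negative, right-skewed, so a
    minority of entity pairs dominates, as in curated association data).
    The 1-entries of Y are the top ``density`` fraction of the planted
    scores. The truth dict carries the factors, the score matrix and the
    threshold for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    A = rng.gamma(shape=2.0, scale=1.0, size=(spec.n, spec.rank))
    B = rng.gamma(shape=2.0, scale=1.0, size=(spec.m, spec.rank))
    score = A @ B.T
    n_pos = int(round(spec.density * spec.n * spec.m))
    n_pos = max(1, min(n_pos, spec.n * spec.m - 1))
    flat = np.sort(score.ravel())[::-1]
    threshold = flat[n_pos - 1]
    Yv = (score >= threshold).astype(float)
    realized = int(Yv.sum())
    if realized != n_pos:  # ties at the threshold; continuous draws make this measure-zero
        warnings.warn(f"requested {n_pos} positives, ties give {realized}")
    row_labels = tuple(f"mirna_{i:04d}" for i in range(spec.n))
    col_labels = tuple(f"disease_{j:04d}" for j in range(spec.m))
    Y = AssociationMatrix(Yv, row_labels, col_labels)
    Sm = SimilarityMatrix(_noisy_similarity(_cosine_rows(A), spec.similarity_noise, rng), row_labels, "miRNA")
    Sd = SimilarityMatrix(_noisy_similarity(_cosine_rows(B), spec.similarity_noise, rng), col_labels, "disease")
    truth = {"A": A, "B": B, "score": score, "threshold": threshold}
    return Y, Sm, Sd, truth


def shuffled_null(Y: AssociationMatrix, seed: int = 0) -> AssociationMatrix:
    """Null dataset: the same number of positives placed uniformly at random.

    Destroys every structural link between the association pattern and any
    similarity matrix, so cross-validated AUC should sit near 0.5.
    """
    rng = np.random.default_rng(seed)
    n_pos = int(Y.values.sum())
    flat = np.zeros(Y.n * Y.m)
    flat[rng.choice(flat.size, size=n_pos, replace=False)] = 1.0
    return AssociationMatrix(flat.reshape(Y.n, Y.m), Y.row_labels, Y.col_labels)


def generate_dags(
    m: int, depth: int, branching: int, seed: int = 0
) -> list[DiseaseDAG]:
    """Random disease DAGs over a shared term hierarchy.

    An internal tree with ``depth - 1`` levels (root at the top, each node
    with ``branching`` children) is generated, and every disease becomes its
    own leaf term attached to a uniformly chosen internal node. Each DAG is
    the disease leaf's ancestor closure; ``depth=1`` gives singleton DAGs.
    """
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    if branching < 1:
        raise ParameterError("branching must be >= 1")
    rng = np.random.default_rng(seed)
    # internal hierarchy: levels 0..depth-2
    parent_of: dict[str, str] = {}
    levels: list[list[str]] = []
    if depth > 1:
        levels.append(["t_root"])
        for lvl in range(1, depth - 1):
            prev = levels[-1]
            cur = []
            for p in prev:
                for b in range(branching):
                    node = f"{p}.{b}"
                    parent_of[node] = p
                    cur.append(node)
            levels.append(cur)
    internal = [node for lvl in levels for node in lvl]
    dags = []
    for j in range(m):
        disease = f"disease_{j:04d}"
        if not internal:
            dags.append(DiseaseDAG(disease, frozenset({disease}), ()))
            continue
        attach = internal[rng.integers(len(internal))]
        nodes = {disease}
        edges = [(disease, attach)]
        node = attach
        nodes.add(node)
        while node in parent_of:
            edges.append((node, parent_of[node]))
            node = parent_of[node]
            nodes.add(node)
        dags.append(DiseaseDAG(disease, frozenset(nodes), tuple(edges)))
    return dags
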