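"""Disease semantic similarity, Gaussian interaction-profile kernels, fusion.

Disease semantic similarity is computed on per-disease directed acyclic
graphs (ancestor closures in a disease ontology): each term in a disease's
DAG contributes semantically, with the disease's own term contributing 1 and
each step towards the root decaying by a factor delta. Two diseases are
similar in proportion to the contributions of the terms their DAGs share.

The GIP kernel measures how alike two entities' binary interaction profiles
are, as a Gaussian radial basis function of the profile distance. The fused
similarity is a convex combination of a precomputed (functional/semantic)
similarity and the GIP kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_io import AssociationMatrix, SimilarityMatrix
from .errors import LabelError, MatrixValidationError, ParameterError

__all__ = [
    "DiseaseDAG",
    "SemanticParams",
    "GipParams",
    "FusionParams",
    "dag_from_edges",
    "semantic_contributions",
    "semantic_value",
    "semantic_similarity",
    "gip_kernel",
    "integrate_similarity",
]


@dataclass(frozen=True)
class DiseaseDAG:
    """Ancestor closure of one disease in a term hierarchy.

    ``edges`` are directed child -> parent pairs restricted to ``nodes``;
    ``term`` is the node representing the disease itself (defaults to the
    disease identifier).
    """

    disease: str
    nodes: frozenset[str]
    edges: tuple[tuple[str, str], ...]
    term: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        if self.term is None:
            object.__setattr__(self, "term", self.disease)
        if self.term not in self.nodes:
            raise MatrixValidationError(
                f"DAG for {self.disease!r}: its own term {self.term!r} is not in the node set"
            )
        for c, p in self.edges:
            if c not in self.nodes or p not in self.nodes:
                raise MatrixValidationError(
                    f"DAG for {self.disease!r}: edge ({c!r}, {p!r}) leaves the node set"
                )
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise MatrixValidationError(f"DAG for {self.disease!r} contains a cycle")
        reachable = {self.term} | nx.descendants(g, self.term)
        if reachable != set(self.nodes):
            stray = set(self.nodes) - reachable
            raise MatrixValidationError(
                f"DAG for {self.disease!r}: nodes {sorted(stray)} are not ancestors of {self.term!r}"
            )

    def graph(self) -> nx.DiGraph:
        """Child->parent digraph over the node set."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class SemanticParams:
    """Semantic contribution factor delta: per-level decay in (0, 1]."""

    delta: float = 0.5

    def __post_init__(self):
        if not 0 < self.delta <= 1:
            raise ParameterError(f"delta must be in (0, 1], got {self.delta}")


@dataclass(frozen=True)
class GipParams:
    """GIP bandwidth: gamma = gamma_prime / mean squared profile norm.

    With ``normalize`` off, gamma_prime is used as the raw bandwidth gamma.
    """

    gamma_prime: float = 1.0
    normalize: bool = True

    def __post_init__(self):
        if self.gamma_prime <= 0:
            raise ParameterError(f"gamma_prime must be positive, got {self.gamma_prime}")


@dataclass(frozen=True)
class FusionParams:
    """Weight alpha on the precomputed similarity; 1-alpha on the GIP kernel."""

    alpha: float = 0.5

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")


def dag_from_edges(
    disease: str, edges: list[tuple[str, str]], term: str | None = None
) -> DiseaseDAG:
    """Build a disease's DAG as the ancestor closure of its term.

    ``edges`` is a global child->parent edge list; only the ancestors of the
    disease's term (and the term itself) end up in the DAG.
    """
    term = disease if term is None else term
    parents: dict[str, list[str]] = {}
    for c, p in edges:
        parents.setdefault(c, []).append(p)
    nodes = {term}
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for p in parents.get(node, ()):  # walk upward to the root(s)
            if p not in nodes:
                nodes.add(p)
                frontier.append(p)
    kept = tuple((c, p) for c, p in edges if c in nodes and p in nodes)
    return DiseaseDAG(disease, frozenset(nodes), kept, term=term)


def semantic_contributions(dag: DiseaseDAG, params: SemanticParams = SemanticParams()) -> dict[str, float]:
    """Per-term semantic contribution within one disease's DAG.

    The disease's own term contributes 1; any other term t contributes
    ``delta * max(contribution of children of t within the DAG)``. Evaluated
    in topological (child-before-parent) order so each child is resolved
    before its parents.
    """
    g = dag.graph()
    contrib: dict[str, float] = {}
    for node in nx.topological_sort(g):
        if node == dag.term:
            contrib[node] = 1.0
        else:
            child_vals = [contrib[c] for c in g.predecessors(node) if c in contrib]
            if not child_vals:
                # unreachable by construction (all nodes are ancestors of the term)
                raise MatrixValidationError(f"term {node!r} has no child inside the DAG")
            contrib[node] = params.delta * max(child_vals)
    return contrib


def semantic_value(dag: DiseaseDAG, params: SemanticParams = SemanticParams()) -> float:
    """Total semantic value of a disease: the sum of its term contributions."""
    return float(sum(semantic_contributions(dag, params).values()))


def semantic_similarity(
    dags: list[DiseaseDAG], params: SemanticParams = SemanticParams()
) -> SimilarityMatrix:
    """Pairwise disease semantic similarity from shared DAG terms.

    S(i, j) sums, over terms shared by the two DAGs, the contributions the
    term makes to each disease, normalized by the sum of the two diseases'
    total semantic values. The diagonal is exactly 1.
    """
    labels = [d.disease for d in dags]
    if len(set(labels)) != len(labels):
        raise MatrixValidationError("duplicate disease labels among DAGs")
    contribs = [semantic_contributions(d, params) for d in dags]
    sv = [sum(c.values()) for c in contribs]
    q = len(dags)
    S = np.eye(q)
    for i in range(q):
        ci = contribs[i]
        for j in range(i + 1, q):
            cj = contribs[j]
            shared = ci.keys() & cj.keys()
            num = sum(ci[t] + cj[t] for t in shared)
            S[i, j] = S[j, i] = num / (sv[i] + sv[j])
    S = np.clip(S, 0.0, 1.0)
    return SimilarityMatrix(S, tuple(labels), "disease")


def gip_kernel(
    Y: AssociationMatrix, axis: str, params: GipParams = GipParams()
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over rows (miRNAs) or columns (diseases).

    GIP(i, j) = exp(-gamma * ||profile_i - profile_j||^2). With
    ``params.normalize`` on, gamma = gamma_prime / mean squared profile norm
    (falling back to gamma_prime when every profile is all-zero).
    """
    if axis == "miRNA":
        profiles, labels = Y.values, Y.row_labels
    elif axis == "disease":
        profiles, labels = Y.values.T, Y.col_labels
    else:
        raise ParameterError(f"axis must be 'miRNA' or 'disease', got {axis!r}")
    gamma = params.gamma_prime
    if params.normalize:
        mean_sq_norm = float(np.mean(np.sum(profiles**2, axis=1)))
        if mean_sq_norm > 0:
            gamma = params.gamma_prime / mean_sq_norm
    if profiles.shape[0] > 1:
        d2 = squareform(pdist(profiles, metric="sqeuclidean"))
    else:
        d2 = np.zeros((1, 1))
    K = np.exp(-gamma * d2)
    np.fill_diagonal(K, 1.0)
    K = (K + K.T) / 2.0
    return SimilarityMatrix(K, labels, axis)


def integrate_similarity(
    S: SimilarityMatrix, G: SimilarityMatrix, params: FusionParams = FusionParams()
) -> SimilarityMatrix:
    """Fused similarity K = alpha * S + (1 - alpha) * G, elementwise."""
    if S.labels != G.labels or S.kind != G.kind:
        raise LabelError("similarity matrices to fuse must share labels and kind")
    K = params.alpha * S.values + (1.0 - params.alpha) * G.values
    return SimilarityMatrix(K, S.labels, S.kind)
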