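import numpy as np
import pytest

from bgcmf.data_io import SimilarityMatrix
from bgcmf.errors import MatrixValidationError, ParameterError
from bgcmf.similarity import (
    DiseaseDAG,
    FusionParams,
    GipParams,
    SemanticParams,
    dag_from_edges,
    gip_kernel,
    integrate_similarity,
    semantic_contributions,
    semantic_similarity,
    semantic_value,
)

from conftest import make_association, make_similarity, random_similarity


def chain_dag(name="D"):
    # P <- C <- D: D is a child of C, C a child of P
    return DiseaseDAG(name, frozenset({name, "C", "P"}), ((name, "C"), ("C", "P")), term=name)


class TestSemanticContributions:
    def test_singleton(self):
        dag = DiseaseDAG("D", frozenset({"D"}), ())
        assert semantic_contributions(dag) == {"D": 1.0}
        assert semantic_value(dag) == 1.0

    def test_chain_decay(self):
        contrib = semantic_contributions(chain_dag(), SemanticParams(delta=0.5))
        assert contrib == {"D": 1.0, "C": 0.5, "P": 0.25}
        assert semantic_value(chain_dag(), SemanticParams(delta=0.5)) == pytest.approx(1.75)

    def test_diamond_max_rule(self):
        # D has parents X and Y, both children of R
        dag = DiseaseDAG(
            "D",
            frozenset({"D", "X", "Y", "R"}),
            (("D", "X"), ("D", "Y"), ("X", "R"), ("Y", "R")),
        )
        contrib = semantic_contributions(dag, SemanticParams(delta=0.5))
        assert contrib["R"] == pytest.approx(0.25)

    def test_delta_one_gives_node_count(self):
        dag = chain_dag()
        assert semantic_value(dag, SemanticParams(delta=1.0)) == 3.0

    def test_cycle_rejected(self):
        with pytest.raises(MatrixValidationError, match="cycle"):
            DiseaseDAG("D", frozenset({"D", "A"}), (("D", "A"), ("A", "D")))

    def test_stray_node_rejected(self):
        with pytest.raises(MatrixValidationError, match="ancestors"):
            DiseaseDAG("D", frozenset({"D", "Z"}), ())


class TestSemanticSimilarity:
    def test_identical_dags_give_one(self):
        """Two diseases mapped to the same term share every contribution."""
        d1 = chain_dag("D")
        twin = DiseaseDAG("D_twin", d1.nodes, d1.edges, term="D")
        S = semantic_similarity([d1, twin])
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_disjoint_dags_give_zero(self):
        d1 = DiseaseDAG("D1", frozenset({"D1"}), ())
        d2 = DiseaseDAG("D2", frozenset({"D2"}), ())
        S = semantic_similarity([d1, d2])
        assert S.values[0, 1] == 0.0

    def test_child_parent_worked_example(self):
        """Child of P vs P itself with delta=0.5: shared term P gives 1.5/2.5 = 0.6."""
        child = DiseaseDAG("D", frozenset({"D", "P"}), (("D", "P"),))
        parent = DiseaseDAG("P", frozenset({"P"}), ())
        S = semantic_similarity([child, parent], SemanticParams(delta=0.5))
        assert S.values[0, 1] == pytest.approx(0.6)
        assert S.values[1, 0] == pytest.approx(0.6)
        np.testing.assert_array_equal(np.diag(S.values), 1.0)

    def test_duplicate_disease_labels_rejected(self):
        d = DiseaseDAG("D", frozenset({"D"}), ())
        with pytest.raises(MatrixValidationError, match="duplicate"):
            semantic_similarity([d, d])

    def test_shared_ancestor_monotonicity(self, rng):
        """Adding a shared ancestor never decreases similarity (brute-force recheck)."""
        for _ in range(20):
            # two sibling diseases under a common parent chain of random length
            L = int(rng.integers(1, 4))
            chain = [f"t{i}" for i in range(L)]
            edges = [(chain[i], chain[i + 1]) for i in range(L - 1)]

            def build(extra_root: bool):
                es = list(edges)
                nodes = set(chain)
                if extra_root:
                    nodes.add("root")
                    es.append((chain[-1], "root"))
                dags = []
                for d in ("A", "B"):
                    dnodes = nodes | {d}
                    des = es + [(d, chain[0])]
                    dags.append(DiseaseDAG(d, frozenset(dnodes), tuple(des)))
                return semantic_similarity(dags).values[0, 1]

            assert build(True) >= build(False) - 1e-12

    def test_matches_bruteforce_recursion(self, rng):
        """Contributions agree with a naive memoized recursion on random DAGs."""
        def naive(dag, delta):
            children = {}
            for c, p in dag.edges:
                children.setdefault(p, []).append(c)

            memo = {}

            def rec(t):
                if t in memo:
                    return memo[t]
                if t == dag.term:
                    memo[t] = 1.0
                else:
                    memo[t] = delta * max(rec(c) for c in children[t] if c in dag.nodes)
                return memo[t]

            return {t: rec(t) for t in dag.nodes}

        for _ in range(25):
            # random layered DAG: term at layer 0, ancestors above
            n_layers = int(rng.integers(2, 5))
            layers = [[f"L{l}N{i}" for i in range(int(rng.integers(1, 4)))] for l in range(n_layers)]
            term = "D"
            layers[0] = [term]
            edges = []
            for l in range(1, n_layers):
                for node in layers[l]:
                    kids = rng.choice(len(layers[l - 1]), size=int(rng.integers(1, len(layers[l - 1]) + 1)), replace=False)
                    for kidx in kids:
                        edges.append((layers[l - 1][kidx], node))
            nodes = frozenset(x for lay in layers for x in lay)
            dag = DiseaseDAG("D", nodes, tuple(edges))
            delta = float(rng.uniform(0.2, 1.0))
            got = semantic_contributions(dag, SemanticParams(delta=delta))
            assert got == pytest.approx(naive(dag, delta))


class TestDagFromEdges:
    def test_ancestor_closure(self):
        edges = [("D", "C"), ("C", "P"), ("X", "P"), ("Q", "D")]
        dag = dag_from_edges("D", edges)
        assert dag.nodes == frozenset({"D", "C", "P"})  # X, Q are not ancestors of D
        assert set(dag.edges) == {("D", "C"), ("C", "P")}


class TestGipKernel:
    def test_identical_profiles_similarity_one(self):
        Y = make_association([[1, 0, 1], [1, 0, 1]])
        K = gip_kernel(Y, "miRNA", GipParams(gamma_prime=3.7, normalize=False))
        assert K.values[0, 1] == 1.0

    def test_orthogonal_profiles_analytic(self):
        Y = make_association([[1, 0], [0, 1]])
        K = gip_kernel(Y, "miRNA", GipParams(gamma_prime=1.0, normalize=False))
        assert K.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_normalization_rule(self):
        """2x2 identity: mean squared norm 1, so gamma = gamma_prime."""
        Y = make_association(np.eye(2))
        K = gip_kernel(Y, "miRNA", GipParams(gamma_prime=1.0, normalize=True))
        assert K.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_all_zero_profiles_fall_back_to_raw_gamma(self):
        Y = make_association(np.zeros((3, 2)))
        K = gip_kernel(Y, "miRNA", GipParams(gamma_prime=2.0, normalize=True))
        np.testing.assert_array_equal(K.values, np.ones((3, 3)))

    @pytest.mark.parametrize("axis", ["miRNA", "disease"])
    def test_matches_bruteforce_double_loop(self, axis, rng):
        for _ in range(25):
            Y = make_association((rng.random((8, 6)) < 0.4).astype(float))
            params = GipParams(gamma_prime=float(rng.uniform(0.2, 3.0)), normalize=bool(rng.integers(2)))
            K = gip_kernel(Y, axis, params)
            profiles = Y.values if axis == "miRNA" else Y.values.T
            gamma = params.gamma_prime
            if params.normalize:
                msn = np.mean([p @ p for p in profiles])
                if msn > 0:
                    gamma = params.gamma_prime / msn
            q = profiles.shape[0]
            expect = np.empty((q, q))
            for i in range(q):
                for j in range(q):
                    d = profiles[i] - profiles[j]
                    expect[i, j] = np.exp(-gamma * (d @ d))
            np.testing.assert_allclose(K.values, expect, atol=1e-12)

    def test_bad_axis(self):
        with pytest.raises(ParameterError):
            gip_kernel(make_association([[1]]), "gene")


class TestIntegrateSimilarity:
    def test_endpoints_and_midpoint(self):
        S = make_similarity([[1, 0.4], [0.4, 1]], "miRNA")
        G = make_similarity([[1, 0.8], [0.8, 1]], "miRNA")
        assert integrate_similarity(S, G, FusionParams(1.0)).values[0, 1] == 0.4
        assert integrate_similarity(S, G, FusionParams(0.0)).values[0, 1] == 0.8
        assert integrate_similarity(S, G, FusionParams(0.5)).values[0, 1] == pytest.approx(0.6)

    def test_preserves_invariants_for_random_alpha(self, rng):
        for _ in range(20):
            S = make_similarity(random_similarity(rng, 6), "disease")
            G = make_similarity(random_similarity(rng, 6), "disease")
            alpha = float(rng.random())
            K = integrate_similarity(S, G, FusionParams(alpha))
            v = K.values
            assert np.allclose(v, v.T)
            assert np.allclose(np.diag(v), 1.0)
            assert v.min() >= 0 and v.max() <= 1

    def test_label_mismatch_rejected(self):
        S = make_similarity(np.eye(2), "miRNA")
        G = SimilarityMatrix(np.eye(2), ("x", "y"), "miRNA")
        from bgcmf.errors import LabelError

        with pytest.raises(LabelError):
            integrate_similarity(S, G)
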