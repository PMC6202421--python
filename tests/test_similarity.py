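"""Semantic similarity models, interaction-profile kernel, and integration."""

import math

import numpy as np
import pytest

from cnmda import (
    ConsistencyError,
    DegenerateDataError,
    DiseaseDAG,
    EntityNamespace,
    ParameterError,
    SimilarityMatrix,
    gip_kernel,
    integrate_disease_similarity,
    integrate_mirna_similarity,
    semantic_contributions,
    semantic_similarity,
    semantic_similarity_matrices,
)
from cnmda.similarity import dag_corpus_counts


def _recursive_contribution_oracle(dag: DiseaseDAG, decay: float) -> dict[str, float]:
    """Literal recursion of the model-1 definition: the disease's own term is
    1, every other term is decay times the max over its children in the DAG."""
    children = dag.children_of()

    def value(d: str) -> float:
        if d == dag.term:
            return 1.0
        return decay * max(value(c) for c in children[d])

    return {d: value(d) for d in dag.nodes}


class TestSemanticModel1:
    def test_single_node_dag(self):
        dag = DiseaseDAG("B", frozenset({"B"}), frozenset())
        c = semantic_contributions(dag, 1, decay=0.5)
        assert c.values == {"B": 1.0} and c.total == 1.0

    def test_two_node_chain(self, chain_dag):
        c = semantic_contributions(chain_dag, 1, decay=0.5)
        assert c.values == {"A": 1.0, "R": 0.5} and c.total == 1.5

    def test_decay_out_of_range(self, chain_dag):
        with pytest.raises(ParameterError):
            semantic_contributions(chain_dag, 1, decay=1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_sweep_matches_recursive_oracle(self, seed):
        """BFS-layered evaluation equals the literal recursion on random DAGs
        of up to 6 nodes."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        nodes = [f"t{i}" for i in range(n)]  # t0 = disease term, rest ancestors
        edges = set()
        for i in range(1, n):  # each ancestor gets >=1 child among lower-index nodes
            for j in rng.choice(i, size=int(rng.integers(1, i + 1)), replace=False):
                edges.add((nodes[i], nodes[int(j)]))  # parent -> child
        dag = DiseaseDAG(nodes[0], frozenset(nodes), frozenset(edges))
        decay = float(rng.uniform(0.1, 0.9))
        got = semantic_contributions(dag, 1, decay=decay).values
        want = _recursive_contribution_oracle(dag, decay)
        assert got.keys() == want.keys()
        assert all(math.isclose(got[k], want[k], rel_tol=1e-12) for k in got)

    def test_relabel_invariance(self, chain_dag):
        relabeled = DiseaseDAG("X", frozenset({"X", "Y"}), frozenset({("Y", "X")}))
        c1 = semantic_contributions(chain_dag, 1, decay=0.5)
        c2 = semantic_contributions(relabeled, 1, decay=0.5)
        assert sorted(c1.values.values()) == sorted(c2.values.values())
        assert c1.total == c2.total


class TestSemanticModel2:
    def test_two_disease_corpus(self, chain_dag):
        # corpus: A with DAG {A, R}; R with DAG {R}. R appears in both DAGs,
        # A in one of two, so A carries information -log(1/2) and R none.
        dag_r = DiseaseDAG("R", frozenset({"R"}), frozenset())
        counts, n = dag_corpus_counts({"A": chain_dag, "R": dag_r})
        assert counts == {"A": 1, "R": 2} and n == 2
        c = semantic_contributions(chain_dag, 2, corpus_counts=counts, n_diseases=n)
        assert c.values["R"] == 0.0
        assert math.isclose(c.values["A"], math.log(2), rel_tol=1e-12)
        assert math.isclose(c.total, math.log(2), rel_tol=1e-12)

    def test_zero_corpus_count_rejected(self, chain_dag):
        with pytest.raises(ConsistencyError):
            semantic_contributions(chain_dag, 2, corpus_counts={"A": 1}, n_diseases=2)


class TestSemanticSimilarity:
    def test_identical_dags_score_one(self, chain_dag):
        c = semantic_contributions(chain_dag, 1, decay=0.5)
        assert semantic_similarity(c, c) == 1.0

    def test_disjoint_dags_score_zero(self, chain_dag):
        other = DiseaseDAG("B", frozenset({"B", "S"}), frozenset({("S", "B")}))
        ca = semantic_contributions(chain_dag, 1, decay=0.5)
        cb = semantic_contributions(other, 1, decay=0.5)
        assert semantic_similarity(ca, cb) == 0.0

    def test_hand_computed_chain_pair(self, chain_dag):
        # A has T = {A, R} with values 1 and 0.5 (DV 1.5); R alone has value 1.
        # Shared term R contributes 0.5 + 1 over denominator 1.5 + 1 -> 0.6.
        dag_r = DiseaseDAG("R", frozenset({"R"}), frozenset())
        ca = semantic_contributions(chain_dag, 1, decay=0.5)
        cr = semantic_contributions(dag_r, 1, decay=0.5)
        assert math.isclose(semantic_similarity(ca, cr), 0.6, rel_tol=1e-12)

    def test_model_mismatch_rejected(self, chain_dag):
        c1 = semantic_contributions(chain_dag, 1, decay=0.5)
        counts, n = dag_corpus_counts({"A": chain_dag})
        c2 = semantic_contributions(chain_dag, 2, corpus_counts=counts, n_diseases=n)
        with pytest.raises(ParameterError):
            semantic_similarity(c1, c2)

    def test_matrix_builder_properties(self):
        diseases = EntityNamespace("disease", ("A", "B", "C"))
        dags = {
            "A": DiseaseDAG("A", frozenset({"A", "R"}), frozenset({("R", "A")})),
            "B": DiseaseDAG("B", frozenset({"B", "R"}), frozenset({("R", "B")})),
        }
        ss1, ss2, has_dag = semantic_similarity_matrices(diseases, dags)
        assert has_dag.tolist() == [True, True, False]
        for s in (ss1.values, ss2.values):
            assert (s == s.T).all() and (np.diag(s) == 1.0).all()
            assert ((0 <= s) & (s <= 1)).all()
        assert ss1.values[0, 1] > 0  # shared root R
        assert ss1.values[0, 2] == 0  # C has no DAG


class TestGipKernel:
    def test_identical_profiles_score_one(self):
        ns = EntityNamespace("disease", ("a", "b"))
        k = gip_kernel(np.array([[1, 0, 1], [1, 0, 1]]), ns)
        assert np.allclose(k.values, 1.0)

    def test_hand_computed_two_profiles(self):
        # mean squared norm (1 + 1)/2 = 1 so gamma = 1; distance^2 = 2.
        ns = EntityNamespace("disease", ("a", "b"))
        k = gip_kernel(np.array([[1, 0], [0, 1]]), ns, gamma_prime=1.0)
        assert math.isclose(k.values[0, 1], math.exp(-2), rel_tol=1e-14)
        assert k.values[0, 0] == k.values[1, 1] == 1.0

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(0)
        profiles = (rng.random((10, 8)) < 0.4).astype(float)
        ns = EntityNamespace("miRNA", tuple(f"m{i}" for i in range(10)))
        gamma_prime = 0.8
        k = gip_kernel(profiles, ns, gamma_prime=gamma_prime)
        gamma = gamma_prime / np.mean([(p ** 2).sum() for p in profiles])
        for u in range(10):
            for v in range(10):
                want = math.exp(-gamma * ((profiles[u] - profiles[v]) ** 2).sum())
                assert abs(k.values[u, v] - want) < 1e-14

    def test_kernel_invariants(self):
        rng = np.random.default_rng(3)
        profiles = (rng.random((12, 9)) < 0.3).astype(float)
        ns = EntityNamespace("lncRNA", tuple(f"l{i}" for i in range(12)))
        k = gip_kernel(profiles, ns)
        assert (np.diag(k.values) == 1.0).all()
        assert np.abs(k.values - k.values.T).max() < 1e-15
        assert ((k.values > 0) & (k.values <= 1)).all()

    def test_all_zero_profiles_rejected(self):
        ns = EntityNamespace("disease", ("a", "b"))
        with pytest.raises(DegenerateDataError):
            gip_kernel(np.zeros((2, 4)), ns)

    def test_invalid_bandwidth_scale(self):
        ns = EntityNamespace("disease", ("a",))
        with pytest.raises(ParameterError):
            gip_kernel(np.ones((1, 2)), ns, gamma_prime=0.0)


class TestIntegration:
    def _mats(self):
        ns = EntityNamespace("disease", ("a", "b"))
        ss1 = SimilarityMatrix(ns, np.array([[1.0, 0.6], [0.6, 1.0]]))
        ss2 = SimilarityMatrix(ns, np.array([[1.0, 0.4], [0.4, 1.0]]))
        kd = SimilarityMatrix(ns, np.array([[1.0, 0.135], [0.135, 1.0]]))
        return ns, ss1, ss2, kd

    def test_semantic_branch_is_mean(self):
        _, ss1, ss2, kd = self._mats()
        sd = integrate_disease_similarity(ss1, ss2, kd, np.ones((2, 2), dtype=bool))
        assert sd.values[0, 1] == pytest.approx(0.5)

    def test_kernel_fallback_branch(self):
        _, ss1, ss2, kd = self._mats()
        mask = np.eye(2, dtype=bool)
        sd = integrate_disease_similarity(ss1, ss2, kd, mask)
        assert sd.values[0, 1] == pytest.approx(0.135)

    def test_kernel_never_read_when_fully_masked(self):
        ns, ss1, ss2, _ = self._mats()
        kd_nan = SimilarityMatrix(ns, np.ones((2, 2)))
        kd_nan.values[:] = np.nan  # poisoned: any read would surface as NaN
        sd = integrate_disease_similarity(ss1, ss2, kd_nan, np.ones((2, 2), dtype=bool))
        assert not np.isnan(sd.values).any()

    def test_asymmetric_mask_rejected(self):
        _, ss1, ss2, kd = self._mats()
        mask = np.array([[True, True], [False, True]])
        with pytest.raises(ConsistencyError):
            integrate_disease_similarity(ss1, ss2, kd, mask)

    def test_mirna_functional_branch_and_fallback(self):
        ns = EntityNamespace("miRNA", ("m1", "m2"))
        fs = SimilarityMatrix(ns, np.array([[1.0, 0.7], [0.7, 1.0]]))
        km = SimilarityMatrix(ns, np.array([[1.0, 0.2], [0.2, 1.0]]))
        assert integrate_mirna_similarity(fs, km).values[0, 1] == pytest.approx(0.7)
        fs0 = SimilarityMatrix(ns, np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert integrate_mirna_similarity(fs0, km).values[0, 1] == pytest.approx(0.2)

    def test_full_fs_coverage_reproduces_fs(self):
        ns = EntityNamespace("miRNA", ("m1", "m2"))
        fs = SimilarityMatrix(ns, np.array([[1.0, 0.7], [0.7, 1.0]]))
        km = SimilarityMatrix(ns, np.array([[1.0, 0.2], [0.2, 1.0]]))
        assert (integrate_mirna_similarity(fs, km).values == fs.values).all()
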