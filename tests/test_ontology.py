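"""Semantic-similarity unit and property tests.

The independent oracle enumerates ancestor sets explicitly and computes
scheme-1 weights as decay**(shortest upward hop count) via networkx
shortest paths — a different route than the package's topological DP.
"""

import math

import networkx as nx
import numpy as np
import pytest

from mdgcn import (
    DiseaseOntology,
    contribution_scheme1,
    contribution_scheme2,
    pairwise_semantic_similarity,
    semantic_similarity_matrix,
    semantic_value,
)
from mdgcn.ontology import InvalidOntologyError

from conftest import random_dag_edges


# ---------------------------------------------------------------- oracle


def oracle_scheme1(edges, d, decay):
    g = nx.DiGraph(edges)  # child -> parent
    dists = nx.single_source_shortest_path_length(g, d)
    return {x: decay**h for x, h in dists.items()}


def oracle_pair_sim(weights_a, weights_b):
    shared = weights_a.keys() & weights_b.keys()
    denom = sum(weights_a.values()) + sum(weights_b.values())
    if not shared or denom == 0:
        return 0.0
    return sum(weights_a[x] + weights_b[x] for x in shared) / denom


# ---------------------------------------------------------------- scheme 1


def test_chain_geometric_decay(chain_ontology):
    cm = contribution_scheme1(chain_ontology, "d", 0.5)
    assert cm.weights == {"d": 1.0, "p": 0.5, "r": 0.25}
    assert semantic_value(cm) == pytest.approx(1.75)


def test_self_weight_is_one(diamond_ontology):
    cm = contribution_scheme1(diamond_ontology, "d", 0.3)
    assert cm.weights["d"] == 1.0


def test_diamond_takes_max_over_paths(diamond_ontology):
    cm = contribution_scheme1(diamond_ontology, "d", 0.5)
    assert cm.weights == {"d": 1.0, "p1": 0.5, "p2": 0.5, "r": 0.25}
    assert semantic_value(cm) == pytest.approx(2.25)


def test_unknown_disease_raises(chain_ontology):
    with pytest.raises(KeyError):
        contribution_scheme1(chain_ontology, "nope", 0.5)


def test_cyclic_ontology_rejected():
    with pytest.raises(InvalidOntologyError):
        DiseaseOntology([("a", "b"), ("b", "a")])


@pytest.mark.parametrize("decay", [0.3, 0.5, 0.8])
def test_scheme1_equals_shortest_hop_oracle_on_random_dags(decay):
    """DP weights == decay**hops on sampled DAGs of up to 8 nodes."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(2, 9))
        edges = random_dag_edges(rng, n)
        onto = DiseaseOntology(edges)
        d = str(n - 1)
        cm = contribution_scheme1(onto, d, decay)
        assert cm.weights == pytest.approx(oracle_scheme1(edges, d, decay))


# ---------------------------------------------------------------- scheme 2


def test_ubiquitous_term_contributes_zero():
    # r is an ancestor of every disease -> information content 0
    onto = DiseaseOntology([("a", "r"), ("b", "r")], disease_terms=["a", "b"])
    cm = contribution_scheme2(onto, "a")
    assert cm.weights["r"] == 0.0


def test_rare_term_natural_log_weight():
    # 4 diseases; each disease term appears in exactly its own DAG
    edges = [(c, "r") for c in "abcd"]
    onto = DiseaseOntology(edges, disease_terms=list("abcd"))
    cm = contribution_scheme2(onto, "a")
    assert cm.weights["a"] == pytest.approx(math.log(4))


def test_weight_decreases_with_document_frequency():
    # x1 covers 1 disease, x2 covers 2, x3 covers 3 (nested chains)
    edges = [("a", "x1"), ("x1", "x2"), ("b", "x2"), ("x2", "x3"), ("c", "x3")]
    onto = DiseaseOntology(edges, disease_terms=["a", "b", "c"])
    cm = contribution_scheme2(onto, "a")
    assert cm.weights["x1"] > cm.weights["x2"] > cm.weights["x3"]


# ---------------------------------------------------------------- pair sim


def test_shared_ancestors_hand_example():
    # X and Y share ancestors {A, R}; hand value 3/7
    edges = [("X", "A"), ("Y", "A"), ("A", "R")]
    onto = DiseaseOntology(edges)
    s = pairwise_semantic_similarity(onto, "X", "Y", scheme=1, decay=0.5)
    assert s == pytest.approx(3 / 7)


def test_self_similarity_is_one(diamond_ontology):
    assert pairwise_semantic_similarity(diamond_ontology, "d", "d", 1) == pytest.approx(1.0)


def test_disjoint_ancestors_give_zero():
    onto = DiseaseOntology([("a", "r1"), ("b", "r2")])
    assert pairwise_semantic_similarity(onto, "a", "b", 1) == 0.0


@pytest.mark.parametrize("scheme", [1, 2])
def test_symmetry_and_bounds_on_random_dags(scheme):
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(3, 9))
        onto = DiseaseOntology(random_dag_edges(rng, n))
        a, b = str(n - 1), str(n - 2)
        s_ab = pairwise_semantic_similarity(onto, a, b, scheme)
        s_ba = pairwise_semantic_similarity(onto, b, a, scheme)
        assert s_ab == s_ba
        assert 0.0 <= s_ab <= 1.0


def test_added_shared_ancestor_never_decreases_similarity():
    rng = np.random.default_rng(11)
    for _ in range(30):
        n = int(rng.integers(3, 8))
        edges = random_dag_edges(rng, n)
        onto = DiseaseOntology(edges)
        a, b = str(n - 1), str(n - 2)
        base = pairwise_semantic_similarity(onto, a, b, 1)
        # new root shared by the top ancestors of both
        extended = edges + [("0", "shared_root")]
        onto2 = DiseaseOntology(extended)
        grown = pairwise_semantic_similarity(onto2, a, b, 1)
        if "0" in onto.ancestors(a) and "0" in onto.ancestors(b):
            assert grown >= base - 1e-12


# ---------------------------------------------------------------- matrix


def test_matrix_matches_bruteforce_oracle():
    """3-disease toy DAG: full matrix equals the enumeration oracle."""
    edges = [("d1", "p"), ("d2", "p"), ("p", "r"), ("d3", "r")]
    onto = DiseaseOntology(edges, disease_terms=["d1", "d2", "d3"])
    decay = 0.5
    m = semantic_similarity_matrix(onto, ["d1", "d2", "d3"], decay)
    # oracle: explicit ancestor sets and both weight schemes
    anc = {"d1": {"d1", "p", "r"}, "d2": {"d2", "p", "r"}, "d3": {"d3", "r"}}
    hops = {
        "d1": {"d1": 0, "p": 1, "r": 2},
        "d2": {"d2": 0, "p": 1, "r": 2},
        "d3": {"d3": 0, "r": 1},
    }
    df = {x: sum(1 for d in anc if x in anc[d]) for d in anc for x in anc[d]}
    n_dis = 3
    for i, a in enumerate(["d1", "d2", "d3"]):
        for j, b in enumerate(["d1", "d2", "d3"]):
            w1a = {x: decay ** hops[a][x] for x in anc[a]}
            w1b = {x: decay ** hops[b][x] for x in anc[b]}
            w2a = {x: -math.log(df[x] / n_dis) for x in anc[a]}
            w2b = {x: -math.log(df[x] / n_dis) for x in anc[b]}
            expected = 0.5 * (oracle_pair_sim(w1a, w1b) + oracle_pair_sim(w2a, w2b))
            assert m.values[i, j] == pytest.approx(expected, abs=1e-12)
    assert np.allclose(m.values, m.values.T)


def test_disconnected_diseases_give_identity_under_scheme1():
    edges = [("d1", "r1"), ("d2", "r2"), ("d3", "r3")]
    onto = DiseaseOntology(edges, disease_terms=["d1", "d2", "d3"])
    m = semantic_similarity_matrix(onto, ["d1", "d2", "d3"], 0.5, scheme="1")
    assert np.allclose(m.values, np.eye(3))


def test_absent_disease_gets_zero_row_and_warning(caplog):
    onto = DiseaseOntology([("d1", "r"), ("d2", "r")], disease_terms=["d1", "d2"])
    with caplog.at_level("WARNING"):
        m = semantic_similarity_matrix(onto, ["d1", "d2", "ghost"], 0.5)
    assert "absent" in caplog.text
    assert not m.defined[2].any()
    assert np.all(m.values[2] == 0)
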