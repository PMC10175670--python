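"""Disease semantic similarity over ontology DAGs.

Each disease term ``d`` induces a directed acyclic graph ``DAG(d)``: the
term itself plus all of its ancestors in the ontology, with the
child->parent edges among them. Two contribution schemes weight each
ancestor ``x`` of ``d``:

* scheme 1 — geometric decay: the term itself contributes 1, and every
  other ancestor contributes ``decay`` times the best contribution among
  its children inside ``DAG(d)`` (for a uniform decay this is
  ``decay ** h`` with ``h`` the minimum downward hop count to ``d``);
* scheme 2 — information content: ancestor ``x`` contributes
  ``-log(n(x) / |D|)`` where ``n(x)`` counts the disease terms whose
  ancestor DAG contains ``x`` and ``|D|`` is the number of disease terms.

The semantic value of a disease is the sum of its contribution weights,
and the similarity of two diseases is the contribution mass of their
shared ancestors normalised by the sum of their semantic values. The
final similarity averages the two schemes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .types import SimilarityMatrix

__all__ = [
    "DiseaseOntology",
    "ContributionMap",
    "contribution_scheme1",
    "contribution_scheme2",
    "semantic_value",
    "pairwise_semantic_similarity",
    "semantic_similarity_matrix",
]

logger = logging.getLogger(__name__)


class InvalidOntologyError(ValueError):
    """The parent graph contains a cycle or is otherwise malformed."""


@dataclass(frozen=True)
class ContributionMap:
    """Per-ancestor contribution weights for one disease term."""

    disease: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("empty contribution map")


class DiseaseOntology:
    """Parent graph over ontology terms, with a designated disease subset.

    Parameters
    ----------
    parent_edges
        Iterable of ``(child, parent)`` term-id pairs.
    disease_terms
        Terms that correspond to diseases in the association matrix.
        Defaults to all terms.
    """

    def __init__(self, parent_edges, disease_terms=None):
        self._graph = nx.DiGraph()  # edges child -> parent
        for child, parent in parent_edges:
            self._graph.add_edge(str(child), str(parent))
        if self._graph.number_of_nodes() == 0:
            raise InvalidOntologyError("ontology has no edges")
        if not nx.is_directed_acyclic_graph(self._graph):
            raise InvalidOntologyError("cycle detected in ontology parent graph")
        self.nodes = frozenset(self._graph.nodes)
        if disease_terms is None:
            self.disease_terms = frozenset(self.nodes)
        else:
            self.disease_terms = frozenset(str(t) for t in disease_terms)
            missing = self.disease_terms - self.nodes
            if missing:
                raise InvalidOntologyError(
                    f"disease terms absent from ontology: {sorted(missing)[:5]}"
                )
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._df_cache: dict[str, int] | None = None

    def __contains__(self, term: str) -> bool:
        return term in self.nodes

    def parents(self, term: str) -> set[str]:
        return set(self._graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self._graph.predecessors(term))

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestor closure of ``term``, including the term itself (v(d))."""
        if term not in self.nodes:
            raise KeyError(f"unknown ontology term: {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term) | {term})
            self._ancestor_cache[term] = cached
        return cached

    def dag_count(self, term: str) -> int:
        """n(x): number of disease terms whose ancestor DAG contains ``term``."""
        if self._df_cache is None:
            counts: dict[str, int] = {}
            for d in self.disease_terms:
                for x in self.ancestors(d):
                    counts[x] = counts.get(x, 0) + 1
            self._df_cache = counts
        return self._df_cache.get(term, 0)


def contribution_scheme1(
    onto: DiseaseOntology, d: str, decay: float = 0.5
) -> ContributionMap:
    """Geometric-decay contribution weights of every ancestor of ``d``.

    ``weights[d] = 1``; every other ancestor ``x`` gets the max of
    ``decay * weights[x']`` over its children ``x'`` inside ``DAG(d)``.
    """
    if d not in onto.disease_terms:
        raise KeyError(f"unknown disease id: {d!r}")
    if not 0.0 < decay < 1.0:
        raise ValueError(f"decay must be in (0, 1), got {decay}")
    dag_nodes = onto.ancestors(d)
    sub = onto._graph.subgraph(dag_nodes)
    weights: dict[str, float] = {d: 1.0}
    # child -> parent topological order guarantees children are weighted
    # before any of their parents.
    for x in nx.topological_sort(sub):
        if x == d:
            continue
        best = max(weights[c] for c in sub.predecessors(x) if c in weights)
        weights[x] = decay * best
    return ContributionMap(disease=d, weights=weights)


def contribution_scheme2(onto: DiseaseOntology, d: str) -> ContributionMap:
    """Information-content contribution weights, natural logarithm.

    Ancestor ``x`` contributes ``-ln(n(x)/|D|)`` with ``n(x)`` the number
    of disease DAGs that contain ``x``. A term appearing in no disease DAG
    has no defined information content.
    """
    if d not in onto.disease_terms:
        raise KeyError(f"unknown disease id: {d!r}")
    n_dis = len(onto.disease_terms)
    weights: dict[str, float] = {}
    for x in onto.ancestors(d):
        n_x = onto.dag_count(x)
        if n_x == 0:
            raise ValueError(f"term {x!r} appears in no disease DAG (log of zero)")
        weights[x] = -math.log(n_x / n_dis)
    return ContributionMap(disease=d, weights=weights)


def semantic_value(cm: ContributionMap) -> float:
    """Sum of all contribution weights (Df of the disease)."""
    return float(sum(cm.weights.values()))


def _pair_similarity(cm_a: ContributionMap, cm_b: ContributionMap) -> float:
    shared = cm_a.weights.keys() & cm_b.weights.keys()
    if not shared:
        return 0.0
    denom = semantic_value(cm_a) + semantic_value(cm_b)
    if denom == 0.0:
        return 0.0
    num = sum(cm_a.weights[x] + cm_b.weights[x] for x in shared)
    return num / denom


def pairwise_semantic_similarity(
    onto: DiseaseOntology, a: str, b: str, scheme: int = 1, decay: float = 0.5
) -> float:
    """Semantic similarity of two diseases under one contribution scheme.

    Symmetric in ``(a, b)`` and bounded in [0, 1]; disjoint ancestor sets
    give 0.
    """
    if scheme == 1:
        cm_a = contribution_scheme1(onto, a, decay)
        cm_b = contribution_scheme1(onto, b, decay)
    elif scheme == 2:
        cm_a = contribution_scheme2(onto, a)
        cm_b = contribution_scheme2(onto, b)
    else:
        raise ValueError(f"scheme must be 1 or 2, got {scheme}")
    return _pair_similarity(cm_a, cm_b)


def semantic_similarity_matrix(
    onto: DiseaseOntology,
    diseases,
    decay: float = 0.5,
    scheme: str = "average",
) -> SimilarityMatrix:
    """Full disease-by-disease semantic similarity matrix.

    ``scheme`` is ``"average"`` (mean of schemes 1 and 2, the default),
    ``"1"`` or ``"2"``. Diseases absent from the ontology get an empty
    ancestor set: similarity 0 everywhere (their ``defined`` mask row is
    False, which later routes them to the Gaussian-kernel fallback).
    """
    diseases = tuple(str(d) for d in diseases)
    n = len(diseases)
    present = [d for d in diseases if d in onto.disease_terms]
    absent = [d for d in diseases if d not in onto.disease_terms]
    if absent:
        logger.warning(
            "%d disease(s) absent from the ontology; semantic similarity "
            "undefined for them (Gaussian fallback applies): %s",
            len(absent),
            absent[:5],
        )
    cm1 = {d: contribution_scheme1(onto, d, decay) for d in present}
    cm2 = {d: contribution_scheme2(onto, d) for d in present}
    values = np.zeros((n, n))
    defined = np.zeros((n, n), dtype=bool)
    idx = {d: i for i, d in enumerate(diseases)}
    for i, a in enumerate(diseases):
        if a not in cm1:
            continue
        for b in diseases[i:]:
            if b not in cm1:
                continue
            j = idx[b]
            if scheme == "1":
                s = _pair_similarity(cm1[a], cm1[b])
            elif scheme == "2":
                s = _pair_similarity(cm2[a], cm2[b])
            elif scheme == "average":
                s = 0.5 * (
                    _pair_similarity(cm1[a], cm1[b]) + _pair_similarity(cm2[a], cm2[b])
                )
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
            values[i, j] = values[j, i] = s
            defined[i, j] = defined[j, i] = True
    return SimilarityMatrix(ids=diseases, values=values, defined=defined)
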