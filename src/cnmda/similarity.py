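"""Disease semantic similarity, Gaussian interaction-profile kernels, and
the integrated disease/miRNA similarity matrices.

Two semantic models operate on per-disease MeSH-style ancestor DAGs:

* model 1 assigns the disease's own term contribution 1 and decays each
  ancestor's contribution by a factor Delta per step away from the disease,
  taking the max over a term's already-valued children;
* model 2 weights a term by its information content,
  ``-log(n_DAGs containing the term / n_DAGs in the corpus)``, so rare
  (specific) terms contribute more.

Either model scores a disease pair as the sum of both diseases'
contributions over the shared ancestor terms, normalized by the two total
semantic values.  Diseases without usable semantic similarity fall back to a
Gaussian kernel on their binary association profiles, whose bandwidth is the
scale ``gamma_prime`` divided by the mean squared profile norm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .types import (
    ConsistencyError,
    DegenerateDataError,
    DiseaseDAG,
    EntityNamespace,
    ParameterError,
    SimilarityMatrix,
)

__all__ = [
    "SemanticContribution",
    "semantic_contributions",
    "semantic_similarity",
    "semantic_similarity_matrices",
    "dag_corpus_counts",
    "gip_kernel",
    "integrate_disease_similarity",
    "integrate_mirna_similarity",
]

logger = logging.getLogger(__name__)


@dataclass
class SemanticContribution:
    """Per-term semantic contributions of one disease's ancestor DAG."""

    disease: str
    model: int  # 1 or 2
    values: dict[str, float]  # term -> contribution
    total: float  # DV, the sum of values over T(D)
    decay: float | None = None  # model 1 only


def semantic_contributions(
    dag: DiseaseDAG,
    model: int,
    *,
    decay: float = 0.5,
    corpus_counts: Mapping[str, int] | None = None,
    n_diseases: int | None = None,
) -> SemanticContribution:
    """Per-term contributions and total semantic value for one disease.

    Model 1 needs ``decay`` in (0, 1): the disease's own term is worth 1 and
    each other term is worth ``decay`` times the max over its children in the
    DAG, evaluated in increasing distance from the disease term so children
    are always valued first.  Model 2 needs ``corpus_counts`` (how many
    diseases' DAGs contain each term) and ``n_diseases`` (corpus size).
    """
    if model == 1:
        if not (0.0 < decay < 1.0):
            raise ParameterError(f"semantic decay must be in (0, 1), got {decay}")
        children = dag.children_of()
        parents = dag.parents_of()
        # breadth-first from the disease term along child->parent edges:
        # a term's children are strictly closer to the disease, hence valued
        # before the term itself.
        values: dict[str, float] = {dag.term: 1.0}
        frontier = [dag.term]
        while frontier:
            nxt = []
            for node in frontier:
                for p in parents[node]:
                    if p not in values:
                        nxt.append(p)
            for p in nxt:
                valued = [values[c] for c in children[p] if c in values]
                if valued:
                    values[p] = decay * max(valued)
            frontier = nxt
        missing = dag.nodes - values.keys()
        if missing:  # ancestors unreachable from the term cannot occur in T(D)
            raise ConsistencyError(
                f"DAG for {dag.disease!r}: nodes {sorted(missing)} unreachable from term"
            )
        return SemanticContribution(dag.disease, 1, values, sum(values.values()), decay)

    if model == 2:
        if corpus_counts is None or n_diseases is None:
            raise ParameterError("model 2 requires corpus_counts and n_diseases")
        values = {}
        for node in dag.nodes:
            count = corpus_counts.get(node, 0)
            if count <= 0:
                raise ConsistencyError(
                    f"corpus count for term {node!r} is 0 although it appears in a DAG"
                )
            values[node] = -math.log(count / n_diseases)
        return SemanticContribution(dag.disease, 2, values, sum(values.values()))

    raise ParameterError(f"semantic model must be 1 or 2, got {model}")


def semantic_similarity(ci: SemanticContribution, cj: SemanticContribution) -> float:
    """Similarity of two diseases under one semantic model.

    ``sum over shared terms of (value_i + value_j) / (DV_i + DV_j)``.
    Self-similarity is 1; a zero total on both sides is guarded (0 for
    distinct diseases, 1 for a disease against itself).
    """
    if ci.model != cj.model:
        raise ParameterError("cannot mix semantic models in one similarity")
    if ci.disease == cj.disease:
        return 1.0
    denom = ci.total + cj.total
    if denom == 0.0:
        return 0.0
    shared = ci.values.keys() & cj.values.keys()
    return sum(ci.values[t] + cj.values[t] for t in shared) / denom


def dag_corpus_counts(dags: Mapping[str, DiseaseDAG]) -> tuple[dict[str, int], int]:
    """How many diseases' DAGs contain each term, and the corpus size."""
    counts: dict[str, int] = {}
    for dag in dags.values():
        for node in dag.nodes:
            counts[node] = counts.get(node, 0) + 1
    return counts, len(dags)


def semantic_similarity_matrices(
    diseases: EntityNamespace,
    dags: Mapping[str, DiseaseDAG],
    *,
    decay: float = 0.5,
) -> tuple[SimilarityMatrix, SimilarityMatrix, np.ndarray]:
    """SS1, SS2 over a disease namespace, plus the has-DAG indicator.

    Diseases without a DAG get zero rows/columns (apart from unit diagonal);
    the boolean vector marks which diseases contributed.  Model-2 information
    content is computed over the corpus of supplied DAGs.
    """
    n = len(diseases)
    has_dag = np.array([d in dags for d in diseases.ids], dtype=bool)
    counts, n_corpus = dag_corpus_counts({d: dags[d] for d in diseases.ids if d in dags})
    c1: dict[str, SemanticContribution] = {}
    c2: dict[str, SemanticContribution] = {}
    for d in diseases.ids:
        if d in dags:
            c1[d] = semantic_contributions(dags[d], 1, decay=decay)
            c2[d] = semantic_contributions(dags[d], 2, corpus_counts=counts, n_diseases=n_corpus)
    ss1 = np.eye(n)
    ss2 = np.eye(n)
    with_dag = [i for i in range(n) if has_dag[i]]
    for a, i in enumerate(with_dag):
        di = diseases.ids[i]
        for j in with_dag[a + 1:]:
            dj = diseases.ids[j]
            ss1[i, j] = ss1[j, i] = semantic_similarity(c1[di], c1[dj])
            ss2[i, j] = ss2[j, i] = semantic_similarity(c2[di], c2[dj])
    return (
        SimilarityMatrix(diseases, ss1, "SS1"),
        SimilarityMatrix(diseases, ss2, "SS2"),
        has_dag,
    )


def gip_kernel(
    profiles: np.ndarray,
    namespace: EntityNamespace,
    *,
    gamma_prime: float = 1.0,
    tag: str = "GIP",
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over binary association profiles.

    ``K(u, v) = exp(-gamma * ||IP(u) - IP(v)||^2)`` with bandwidth
    ``gamma = gamma_prime / mean_u ||IP(u)||^2``; one implementation serves
    the disease, miRNA and lncRNA kernels.
    """
    if gamma_prime <= 0:
        raise ParameterError(f"gamma_prime must be positive, got {gamma_prime}")
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] != len(namespace):
        raise ConsistencyError(
            f"profile matrix shape {profiles.shape} does not match namespace size {len(namespace)}"
        )
    mean_sq_norm = float((profiles ** 2).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise DegenerateDataError(
            f"{tag}: all interaction profiles are zero; kernel bandwidth undefined"
        )
    gamma = gamma_prime / mean_sq_norm
    if len(namespace) == 1:
        values = np.ones((1, 1))
    else:
        sq = squareform(pdist(profiles, metric="sqeuclidean"))
        values = np.exp(-gamma * sq)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(namespace, values, tag)


def integrate_disease_similarity(
    ss1: SimilarityMatrix,
    ss2: SimilarityMatrix,
    kd: SimilarityMatrix,
    has_semantic: np.ndarray,
) -> SimilarityMatrix:
    """Integrated disease similarity: mean of the two semantic models where a
    pair has semantic similarity, Gaussian kernel otherwise.

    ``has_semantic`` is the boolean pair mask; it must be symmetric.
    """
    if not (ss1.namespace.ids == ss2.namespace.ids == kd.namespace.ids):
        raise ConsistencyError("SS1/SS2/KD namespaces differ")
    has_semantic = np.asarray(has_semantic, dtype=bool)
    if has_semantic.shape != ss1.values.shape:
        raise ConsistencyError("semantic mask shape mismatch")
    if not (has_semantic == has_semantic.T).all():
        raise ConsistencyError("semantic pair mask is asymmetric")
    values = np.where(has_semantic, (ss1.values + ss2.values) / 2.0, kd.values)
    return SimilarityMatrix(ss1.namespace, values, "SD")


def integrate_mirna_similarity(
    fs: SimilarityMatrix | None,
    km: SimilarityMatrix,
    has_functional: np.ndarray | None = None,
) -> SimilarityMatrix:
    """Integrated miRNA similarity: functional similarity where available
    (positive entry in the supplied matrix), Gaussian kernel otherwise."""
    if fs is None:
        return SimilarityMatrix(km.namespace, km.values.copy(), "Sm")
    if fs.namespace.ids != km.namespace.ids:
        raise ConsistencyError("FS/KM namespaces differ")
    if has_functional is None:
        has_functional = fs.values > 0
    has_functional = np.asarray(has_functional, dtype=bool)
    if not (has_functional == has_functional.T).all():
        raise ConsistencyError("functional pair mask is asymmetric")
    values = np.where(has_functional, fs.values, km.values)
    return SimilarityMatrix(km.namespace, values, "Sm")
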