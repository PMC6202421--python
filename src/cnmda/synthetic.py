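"""Synthetic tripartite datasets with planted co-module structure.

The generator emulates, at desk scale, the statistical shape of the curated
resources the model was designed for: sparse binary association matrices
between lncRNAs, diseases and miRNAs; a MeSH-style rooted disease
hierarchy; and a functional-similarity matrix over miRNAs.  Entities are
partitioned into co-modules ("groups"); association probability is
``p_within`` for a pair of entities in the same group and ``p_background``
otherwise, so a hidden disease-miRNA link is recoverable from the shared
lncRNA neighbourhood and similarity structure of its group.  Diseases in
one group share deeper common ancestors in the generated hierarchy than
cross-group pairs, and the functional-similarity matrix is boosted within
groups — mirroring the assumption that similar diseases involve similar
miRNAs.

Randomness: one RNG stream per artifact (associations, hierarchy,
functional similarity), each derived from the master seed by a fixed
offset, so changing one shape parameter never perturbs unrelated draws.
Equal seeds produce bit-identical datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import (
    AssociationMatrix,
    Dataset,
    DegenerateDataError,
    DiseaseDAG,
    EntityNamespace,
    ParameterError,
    SimilarityMatrix,
)

__all__ = ["SyntheticSpec", "GroupLabels", "generate_dataset", "generate_dags", "generate_fs"]

logger = logging.getLogger(__name__)

# fixed per-artifact seed offsets (see module docstring)
_OFFSET_ASSOC = 0
_OFFSET_DAG = 1_000_003
_OFFSET_FS = 2_000_003


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape parameters of a synthetic dataset.

    Defaults give a 20-lncRNA / 30-disease / 40-miRNA network with three
    planted co-modules, dense enough inside a module (p_within = 0.5) and
    sparse outside (p_background = 0.02) for the planted signal to dominate.
    """

    nl: int = 20
    nd: int = 30
    nm: int = 40
    n_groups: int = 3
    p_within: float = 0.5
    p_background: float = 0.02
    dag_depth: int = 3
    dag_branching: int = 2
    fs_signal: float = 0.5
    dag_coverage: float = 1.0  # fraction of diseases given a DAG
    seed: int = 7

    def __post_init__(self) -> None:
        if min(self.nl, self.nd, self.nm) < 1 or self.n_groups < 1:
            raise ParameterError("layer sizes and n_groups must be >= 1")
        if not (0.0 <= self.p_background <= self.p_within <= 1.0):
            raise ParameterError("need 0 <= p_background <= p_within <= 1")
        if self.p_background == self.p_within == 0.0:
            raise ParameterError("p_within = p_background = 0 leaves the network empty")
        if self.dag_depth < 0 or self.dag_branching < 1:
            raise ParameterError("dag_depth >= 0 and dag_branching >= 1 required")
        if not (0.0 <= self.fs_signal <= 1.0) or not (0.0 <= self.dag_coverage <= 1.0):
            raise ParameterError("fs_signal and dag_coverage must be in [0, 1]")


@dataclass
class GroupLabels:
    """Planted co-module index of every entity, for ground-truth tests."""

    lncrna: np.ndarray
    disease: np.ndarray
    mirna: np.ndarray


def _group_assign(n: int, n_groups: int) -> np.ndarray:
    """Deterministic round-robin-ish contiguous assignment of n entities."""
    return (np.arange(n) * n_groups) // n


def _planted_block(
    rng: np.random.Generator,
    rows: np.ndarray,
    cols: np.ndarray,
    p_within: float,
    p_background: float,
) -> np.ndarray:
    same = rows[:, None] == cols[None, :]
    p = np.where(same, p_within, p_background)
    return (rng.random(p.shape) < p).astype(np.uint8)


def generate_dataset(spec: SyntheticSpec) -> tuple[Dataset, GroupLabels]:
    """Draw a full dataset (associations, hierarchy, functional similarity)
    plus the planted group labels.

    Entities that come out isolated (no association in any layer they touch)
    are re-wired with exactly one uniformly chosen edge, because the kernel
    bandwidth normalization assumes non-degenerate interaction profiles.
    """
    rng = np.random.default_rng(spec.seed + _OFFSET_ASSOC)
    lncrnas = EntityNamespace("lncRNA", tuple(f"l{i:03d}" for i in range(spec.nl)))
    diseases = EntityNamespace("disease", tuple(f"d{i:03d}" for i in range(spec.nd)))
    mirnas = EntityNamespace("miRNA", tuple(f"m{i:03d}" for i in range(spec.nm)))
    g_l = _group_assign(spec.nl, spec.n_groups)
    g_d = _group_assign(spec.nd, spec.n_groups)
    g_m = _group_assign(spec.nm, spec.n_groups)

    mda = _planted_block(rng, g_d, g_m, spec.p_within, spec.p_background)  # disease x miRNA
    lda = _planted_block(rng, g_d, g_l, spec.p_within, spec.p_background)  # disease x lncRNA
    mli = _planted_block(rng, g_m, g_l, spec.p_within, spec.p_background)  # miRNA x lncRNA

    # re-wire isolated entities with one random edge each
    for d in np.nonzero((mda.sum(axis=1) == 0) & (lda.sum(axis=1) == 0))[0]:
        mda[d, rng.integers(spec.nm)] = 1
    for m in np.nonzero((mda.sum(axis=0) == 0) & (mli.sum(axis=1) == 0))[0]:
        mda[rng.integers(spec.nd), m] = 1
    for l in np.nonzero((lda.sum(axis=0) == 0) & (mli.sum(axis=0) == 0))[0]:
        lda[rng.integers(spec.nd), l] = 1
    # kernel bandwidths need at least one edge per profile source
    if mda.sum() == 0:
        mda[rng.integers(spec.nd), rng.integers(spec.nm)] = 1
    if lda.sum() == 0:
        lda[rng.integers(spec.nd), rng.integers(spec.nl)] = 1
    if mda.sum() == 0 or lda.sum() == 0:
        raise DegenerateDataError("generated dataset has an empty association layer")

    dags = generate_dags(spec, diseases, g_d)
    labels = GroupLabels(g_l, g_d, g_m)
    fs = generate_fs(spec, mirnas, g_m)
    dataset = Dataset(
        AssociationMatrix(diseases, mirnas, mda),
        AssociationMatrix(diseases, lncrnas, lda),
        AssociationMatrix(mirnas, lncrnas, mli),
        dags=dags,
        fs=fs,
    )
    logger.info(
        "synthetic dataset (seed %d): %d MDAs, %d LDAs, %d MLIs, %d DAGs",
        spec.seed, int(mda.sum()), int(lda.sum()), int(mli.sum()), len(dags),
    )
    return dataset, labels


def generate_dags(
    spec: SyntheticSpec,
    diseases: EntityNamespace | None = None,
    groups: np.ndarray | None = None,
) -> dict[str, DiseaseDAG]:
    """MeSH-like rooted ancestor DAGs with group-shared ancestry.

    All DAGs share one root.  Each group owns ``dag_branching`` ancestor
    chains of length ``dag_depth`` hanging off the root, sharing all but
    their last node; a disease attaches below a randomly chosen chain of
    its group.  Same-group diseases therefore share ``dag_depth`` or more
    ancestors while cross-group pairs share only the root — so semantic
    similarity recovers the planted grouping.  ``dag_depth = 0``
    degenerates to every disease sitting at the root itself (identical
    one-node DAGs, similarity 1 everywhere).
    """
    rng = np.random.default_rng(spec.seed + _OFFSET_DAG)
    if diseases is None:
        diseases = EntityNamespace("disease", tuple(f"d{i:03d}" for i in range(spec.nd)))
    if groups is None:
        groups = _group_assign(len(diseases), spec.n_groups)
    root = "ROOT"
    covered = rng.random(len(diseases)) < spec.dag_coverage
    dags: dict[str, DiseaseDAG] = {}
    for i, d in enumerate(diseases.ids):
        if not covered[i]:
            continue
        if spec.dag_depth == 0:
            dags[d] = DiseaseDAG(d, frozenset({root}), frozenset(), term=root)
            continue
        g = int(groups[i])
        branch = int(rng.integers(spec.dag_branching))
        chain = [root] + [f"A{g}_{k}" for k in range(1, spec.dag_depth)]
        chain.append(f"A{g}_{spec.dag_depth}b{branch}")
        nodes = set(chain) | {d}
        edges = {(chain[k], chain[k + 1]) for k in range(len(chain) - 1)}
        edges.add((chain[-1], d))
        dags[d] = DiseaseDAG(d, frozenset(nodes), frozenset(edges))
    return dags


def generate_fs(
    spec: SyntheticSpec,
    mirnas: EntityNamespace | None = None,
    groups: np.ndarray | None = None,
) -> SimilarityMatrix:
    """Synthetic functional-similarity matrix over miRNAs.

    An exchangeable non-negative background (symmetrized uniform draws on
    [0, 0.3]) plus ``fs_signal`` added to same-group pairs, clipped to
    [0, 1], unit diagonal.  Stands in for a curated functional-similarity
    resource; it reproduces only the group structure, not any real score
    distribution.
    """
    rng = np.random.default_rng(spec.seed + _OFFSET_FS)
    if mirnas is None:
        mirnas = EntityNamespace("miRNA", tuple(f"m{i:03d}" for i in range(spec.nm)))
    if groups is None:
        groups = _group_assign(len(mirnas), spec.n_groups)
    n = len(mirnas)
    base = rng.uniform(0.0, 0.3, size=(n, n))
    base = (base + base.T) / 2.0
    same = groups[:, None] == groups[None, :]
    values = np.clip(base + spec.fs_signal * same, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(mirnas, values, "FS")
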