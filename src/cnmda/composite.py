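"""Assembly of the three-layer composite network and its block transition
matrix.

The composite adjacency W stacks, in fixed order lncRNA / disease / miRNA,
the three within-layer similarity matrices on the diagonal and the binary
association matrices off the diagonal (transposes derived, never stored).

The walker's transition matrix M is built per node: a node that has
associations into another layer reserves jump mass for that layer (x
between lncRNA and disease, y between lncRNA and miRNA, z between disease
and miRNA), distributed uniformly over its associations; whatever mass
remains stays within the layer, spread proportionally to the similarity
row.  Rows of the full matrix therefore always sum to 1: within-layer
similarity rows cannot vanish because the Gaussian kernel is strictly
positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .types import (
    AssociationMatrix,
    ConsistencyError,
    ParameterError,
    SimilarityMatrix,
)

__all__ = [
    "CompositeNetwork",
    "CompositeTransition",
    "assemble_composite",
    "build_transition",
    "row_stochastic_check",
]

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-12


@dataclass
class CompositeNetwork:
    """Blockwise composite adjacency: similarities within layers, binary
    associations across layers.  Association blocks are kept sparse."""

    w_l: SimilarityMatrix  # lncRNA kernel similarity
    w_d: SimilarityMatrix  # integrated disease similarity
    w_m: SimilarityMatrix  # integrated miRNA similarity
    w_ld: sp.csr_array  # lncRNA x disease
    w_dm: sp.csr_array  # disease x miRNA
    w_lm: sp.csr_array  # lncRNA x miRNA

    @property
    def n_l(self) -> int:
        return len(self.w_l.namespace)

    @property
    def n_d(self) -> int:
        return len(self.w_d.namespace)

    @property
    def n_m(self) -> int:
        return len(self.w_m.namespace)

    @property
    def n_nodes(self) -> int:
        return self.n_l + self.n_d + self.n_m

    def node_ids(self) -> list[str]:
        """Node labels in composite order (lncRNAs, diseases, miRNAs)."""
        return list(self.w_l.namespace.ids) + list(self.w_d.namespace.ids) + list(self.w_m.namespace.ids)

    def full_matrix(self) -> np.ndarray:
        """Dense symmetric composite adjacency (for inspection/tests)."""
        w_ld = self.w_ld.toarray()
        w_dm = self.w_dm.toarray()
        w_lm = self.w_lm.toarray()
        return np.block([
            [self.w_l.values, w_ld, w_lm],
            [w_ld.T, self.w_d.values, w_dm],
            [w_lm.T, w_dm.T, self.w_m.values],
        ])


def assemble_composite(
    kl: SimilarityMatrix,
    sd: SimilarityMatrix,
    sm: SimilarityMatrix,
    lda: AssociationMatrix,
    mda: AssociationMatrix,
    mli: AssociationMatrix,
) -> CompositeNetwork:
    """Stack the six inputs into a composite network, checking namespaces.

    ``lda`` is disease x lncRNA and ``mli`` miRNA x lncRNA, as loaded; they
    are transposed here into the lncRNA-row orientation of the composite.
    """
    if sd.namespace.ids != lda.rows.ids or sd.namespace.ids != mda.rows.ids:
        raise ConsistencyError("disease namespace mismatch in block SD/LDA/MDA")
    if sm.namespace.ids != mda.cols.ids or sm.namespace.ids != mli.rows.ids:
        raise ConsistencyError("miRNA namespace mismatch in block Sm/MDA/MLI")
    if kl.namespace.ids != lda.cols.ids or kl.namespace.ids != mli.cols.ids:
        raise ConsistencyError("lncRNA namespace mismatch in block KL/LDA/MLI")
    net = CompositeNetwork(
        w_l=kl,
        w_d=sd,
        w_m=sm,
        w_ld=sp.csr_array(lda.values.T.astype(float)),
        w_dm=sp.csr_array(mda.values.astype(float)),
        w_lm=sp.csr_array(mli.values.T.astype(float)),
    )
    logger.info(
        "composite network: %d lncRNAs + %d diseases + %d miRNAs = %d nodes",
        net.n_l, net.n_d, net.n_m, net.n_nodes,
    )
    return net


@dataclass
class CompositeTransition:
    """Row-stochastic transition matrix of the composite walk, stored as one
    dense array plus the node bookkeeping needed to slice layer blocks."""

    matrix: np.ndarray  # (n_nodes, n_nodes), rows sum to 1
    n_l: int
    n_d: int
    n_m: int
    x: float
    y: float
    z: float
    node_ids: list[str]

    def block(self, from_layer: str, to_layer: str) -> np.ndarray:
        """One of the nine layer blocks, layers named 'l', 'd', 'm'."""
        sl = {"l": slice(0, self.n_l),
              "d": slice(self.n_l, self.n_l + self.n_d),
              "m": slice(self.n_l + self.n_d, self.n_l + self.n_d + self.n_m)}
        return self.matrix[sl[from_layer], sl[to_layer]]


def _jump_block(assoc: sp.csr_array, jump: float) -> np.ndarray:
    """Distribute ``jump`` uniformly over each row's associations; zero rows
    stay zero."""
    a = assoc.toarray()
    row_sums = a.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(row_sums > 0, jump * a / row_sums, 0.0)
    return out


def build_transition(
    net: CompositeNetwork,
    x: float = 1.0 / 3.0,
    y: float = 1.0 / 3.0,
    z: float = 1.0 / 3.0,
    *,
    drop_self_loops: bool = False,
) -> CompositeTransition:
    """Turn a composite network into the row-stochastic transition matrix.

    Per node, the within-layer residual mass is 1 minus the jump parameters
    of the other layers it actually connects to (an lncRNA keeps
    ``1 - x*[has LDA] - y*[has MLI]``, a disease ``1 - x*[has LDA] -
    z*[has MDA]``, a miRNA ``1 - y*[has MLI] - z*[has MDA]``), spread over
    the normalized similarity row; each cross-layer block row distributes
    its jump parameter uniformly over the node's associations.

    ``drop_self_loops`` zeroes similarity diagonals before normalization, a
    common variant of restart walks; the default keeps them, treating the
    similarity rows exactly as written.
    """
    for name, v in (("x", x), ("y", y), ("z", z)):
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"jump probability {name}={v} outside [0, 1]")
    for name, s in (("x+y", x + y), ("x+z", x + z), ("y+z", y + z)):
        if s > 1.0 + 1e-12:
            raise ParameterError(f"jump probabilities {name}={s} exceed 1")

    has_lda_l = np.asarray(net.w_ld.sum(axis=1) > 0).ravel()  # lncRNA side
    has_mli_l = np.asarray(net.w_lm.sum(axis=1) > 0).ravel()
    has_lda_d = np.asarray(net.w_ld.sum(axis=0) > 0).ravel()  # disease side
    has_mda_d = np.asarray(net.w_dm.sum(axis=1) > 0).ravel()
    has_mda_m = np.asarray(net.w_dm.sum(axis=0) > 0).ravel()  # miRNA side
    has_mli_m = np.asarray(net.w_lm.sum(axis=0) > 0).ravel()

    def within(sim: SimilarityMatrix, keep: np.ndarray, tag: str) -> np.ndarray:
        w = sim.values.copy()
        if drop_self_loops:
            np.fill_diagonal(w, 0.0)
        row_sums = w.sum(axis=1, keepdims=True)
        if (row_sums <= 0).any():
            raise ConsistencyError(
                f"{tag}: within-layer similarity row sums to 0; cannot normalize "
                "(should be impossible with a Gaussian-kernel fallback)"
            )
        return keep[:, None] * w / row_sums

    m_l = within(net.w_l, 1.0 - x * has_lda_l - y * has_mli_l, "lncRNA layer")
    m_d = within(net.w_d, 1.0 - x * has_lda_d - z * has_mda_d, "disease layer")
    m_m = within(net.w_m, 1.0 - y * has_mli_m - z * has_mda_m, "miRNA layer")

    m_ld = _jump_block(net.w_ld, x)
    m_lm = _jump_block(net.w_lm, y)
    m_dl = _jump_block(net.w_ld.T.tocsr(), x)
    m_dm = _jump_block(net.w_dm, z)
    m_ml = _jump_block(net.w_lm.T.tocsr(), y)
    m_md = _jump_block(net.w_dm.T.tocsr(), z)

    matrix = np.block([
        [m_l, m_ld, m_lm],
        [m_dl, m_d, m_dm],
        [m_ml, m_md, m_m],
    ])
    t = CompositeTransition(matrix, net.n_l, net.n_d, net.n_m, x, y, z, net.node_ids())
    bad = row_stochastic_check(t)
    if bad:
        node, s = bad[0]
        raise ConsistencyError(f"transition row for {node!r} sums to {s!r}, not 1")
    return t


def row_stochastic_check(t: CompositeTransition, tol: float = ROW_SUM_TOL) -> list[tuple[str, float]]:
    """Rows of the full transition matrix whose sum deviates from 1 by more
    than ``tol``; empty list means the matrix is row-stochastic."""
    sums = t.matrix.sum(axis=1)
    bad = np.nonzero(np.abs(sums - 1.0) > tol)[0]
    return [(t.node_ids[i], float(sums[i])) for i in bad]


def write_transition_tsv(path: str | Path, t: CompositeTransition, *, threshold: float = 0.0) -> None:
    """Dump non-zero transition probabilities as from-node/to-node/probability."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("from\tto\tprobability\n")
        for i, j in zip(*np.nonzero(t.matrix > threshold)):
            fh.write(f"{t.node_ids[i]}\t{t.node_ids[j]}\t{t.matrix[i, j]:.17g}\n")
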