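"""High-level orchestration: from a dataset to similarities, the composite
transition matrix, and ranked predictions."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import similarity as sim
from .composite import CompositeNetwork, CompositeTransition, assemble_composite, build_transition
from .rwr import RankedPredictions, RWRState, build_seed, rank_mirnas, rwr_iterate
from .types import Dataset, ParameterError, SimilarityMatrix

__all__ = ["Params", "build_similarities", "build_model", "predict"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Params:
    """All tunable parameters of the model, at their published defaults.

    delta
        restart probability of the walk (0.7).
    x, y, z
        jump probabilities between the lncRNA/disease, lncRNA/miRNA and
        disease/miRNA layers (all 1/3).
    alpha, beta
        seed-block weights for the lncRNA and disease blocks; the miRNA
        block gets the remainder (all three 1/3 by default).
    decay
        semantic-contribution decay of disease model 1 (0.5).
    gamma_d, gamma_m, gamma_l
        bandwidth scales of the three interaction-profile kernels (1.0).
    lncrna_profile
        which association profile defines the lncRNA kernel: ``"disease"``
        (columns of the lncRNA-disease matrix, default) or ``"mirna"``.
    tol, max_iter
        L1 stopping tolerance (1e-6) and iteration cap of the walk.
    drop_self_loops
        zero similarity diagonals before row normalization (off by default).
    """

    delta: float = 0.7
    x: float = 1.0 / 3.0
    y: float = 1.0 / 3.0
    z: float = 1.0 / 3.0
    alpha: float = 1.0 / 3.0
    beta: float = 1.0 / 3.0
    decay: float = 0.5
    gamma_d: float = 1.0
    gamma_m: float = 1.0
    gamma_l: float = 1.0
    lncrna_profile: str = "disease"
    tol: float = 1e-6
    max_iter: int = 1000
    drop_self_loops: bool = False

    def with_(self, **kwargs) -> "Params":
        return replace(self, **kwargs)


def build_similarities(
    dataset: Dataset, params: Params = Params()
) -> tuple[SimilarityMatrix, SimilarityMatrix, SimilarityMatrix]:
    """Integrated disease similarity, integrated miRNA similarity, and the
    lncRNA kernel, ready for composite assembly.

    Semantic disease similarity (both models, averaged) is used for pairs
    where both diseases carry a DAG and the models assign a positive score;
    other pairs, and all pairs when no DAGs are supplied, fall back to the
    interaction-profile kernel.  miRNA pairs use the functional-similarity
    matrix where it has a positive entry, the kernel otherwise.
    """
    kd = sim.gip_kernel(
        dataset.mda.values, dataset.diseases, gamma_prime=params.gamma_d, tag="KD"
    )
    km = sim.gip_kernel(
        dataset.mda.values.T, dataset.mirnas, gamma_prime=params.gamma_m, tag="KM"
    )
    if params.lncrna_profile == "disease":
        l_profiles = dataset.lda.values.T
    elif params.lncrna_profile == "mirna":
        l_profiles = dataset.mli.values.T
    else:
        raise ParameterError(
            f"lncrna_profile must be 'disease' or 'mirna', got {params.lncrna_profile!r}"
        )
    kl = sim.gip_kernel(l_profiles, dataset.lncrnas, gamma_prime=params.gamma_l, tag="KL")

    if dataset.dags:
        ss1, ss2, has_dag = sim.semantic_similarity_matrices(
            dataset.diseases, dataset.dags, decay=params.decay
        )
        pair_has_dag = np.outer(has_dag, has_dag)
        mask = pair_has_dag & ((ss1.values + ss2.values) > 0)
        sd = sim.integrate_disease_similarity(ss1, ss2, kd, mask)
    else:
        sd = SimilarityMatrix(dataset.diseases, kd.values.copy(), "SD")
    s_m = sim.integrate_mirna_similarity(dataset.fs, km)
    return sd, s_m, kl


def build_model(
    dataset: Dataset, params: Params = Params()
) -> tuple[CompositeNetwork, CompositeTransition]:
    """Similarities -> composite network -> transition matrix."""
    sd, s_m, kl = build_similarities(dataset, params)
    net = assemble_composite(kl, sd, s_m, dataset.lda, dataset.mda, dataset.mli)
    t = build_transition(net, params.x, params.y, params.z, drop_self_loops=params.drop_self_loops)
    return net, t


def predict(
    dataset: Dataset,
    query_disease: str,
    params: Params = Params(),
    *,
    exclude_known: bool = True,
    transition: CompositeTransition | None = None,
) -> tuple[RankedPredictions, RWRState]:
    """Rank candidate miRNAs for one disease.

    Builds the model (unless a prebuilt ``transition`` is passed), runs the
    restart walk seeded at the disease, and ranks miRNAs by their
    stationary probability.
    """
    if transition is None:
        _, transition = build_model(dataset, params)
    p0 = build_seed(query_disease, dataset, params.alpha, params.beta)
    state = rwr_iterate(
        transition, p0, params.delta, params.tol, params.max_iter, params.alpha, params.beta
    )
    preds = rank_mirnas(state, dataset, query_disease, exclude_known=exclude_known)
    logger.info(
        "predicted %d candidates for %r in %d iterations (residual %.3g)",
        len(preds.entries), query_disease, state.iterations, state.residual,
    )
    return preds, state
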