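"""Cross-validation of the predictor over known miRNA-disease associations.

Protocol: each known association (or fold of associations) is masked out of
the disease-miRNA matrix, the model is rebuilt on the masked data, a walk is
run from every disease, and the hidden pair's score is ranked against the
scores of all unlabeled disease-miRNA pairs (the global candidate set; a
per-disease candidate set is available as an option).  The area under the
ROC curve is then the rank-sum (Mann-Whitney) statistic of the hidden
pairs against the candidates, with ties counted half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pipeline import Params, build_similarities
from .composite import assemble_composite, build_transition
from .rwr import ConvergenceError, build_seed, stationary_matrix
from .types import AssociationMatrix, Dataset, ParameterError

__all__ = ["RankRecord", "CVResult", "loocv", "kfold_cv", "roc_auc", "new_disease_ranks"]

logger = logging.getLogger(__name__)


@dataclass
class RankRecord:
    """Rank of one hidden association among the candidate pairs."""

    disease: str
    mirna: str
    score: float
    rank: float  # midrank among candidates + itself, in [1, n_candidates + 1]
    n_candidates: int


@dataclass
class CVResult:
    scheme: str  # "LOOCV" or "k-fold"
    auc: float
    records: list[RankRecord]
    k: int | None = None
    reps: int | None = None
    seed: int | None = None
    rep_aucs: list[float] = field(default_factory=list)
    auc_sd: float | None = None  # across repetitions (k-fold)
    auc_sd_folds: float | None = None  # across folds, pooled over reps
    failed_folds: list[tuple[str, str]] = field(default_factory=list)


def roc_auc(
    positive_ranks: Sequence[float],
    n_candidates: int | Sequence[int],
) -> tuple[float, np.ndarray]:
    """AUC and ROC points from the ranks of hidden positives.

    Each positive carries a (mid)rank among ``n_candidates`` negatives plus
    itself; its AUC contribution is the fraction of negatives it outranks,
    ``(n + 1 - rank) / n``, which is the rank-sum identity with ties counted
    half.  The overall AUC is the mean over positives.  The second return
    value is an array of (FPR, TPR) points obtained by sweeping the rank
    threshold, for plotting.
    """
    ranks = np.asarray(positive_ranks, dtype=float)
    if ranks.size == 0:
        raise ParameterError("AUC undefined: no positive ranks supplied")
    ns = np.broadcast_to(np.asarray(n_candidates, dtype=float), ranks.shape)
    if (ns < 1).any():
        raise ParameterError("need at least one candidate")
    if (ranks < 1).any() or (ranks > ns + 1).any():
        raise ParameterError("ranks must lie in [1, n_candidates + 1]")
    auc = float(((ns + 1.0 - ranks) / ns).mean())
    # threshold sweep on the normalized rank scale
    grid = np.unique(np.concatenate([[0.0, 1.0], (ranks / (ns + 1.0))]))
    curve = np.array([[g, float((ranks / (ns + 1.0) <= g).mean())] for g in grid])
    return auc, curve


def _mask_pairs(mda: AssociationMatrix, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    values = mda.values.copy()
    for d, m in pairs:
        values[d, m] = 0
    return values


def _score_all(dataset: Dataset, params: Params, sims=None) -> np.ndarray:
    """Disease x miRNA stationary-score matrix: one restart walk per disease,
    batched; entry (d, m) is miRNA m's stationary probability for seed d."""
    if sims is None:
        sd, s_m, kl = build_similarities(dataset, params)
    else:
        sd, s_m, kl = sims
    net = assemble_composite(kl, sd, s_m, dataset.lda, dataset.mda, dataset.mli)
    t = build_transition(net, params.x, params.y, params.z, drop_self_loops=params.drop_self_loops)
    seeds = np.column_stack(
        [build_seed(d, dataset, params.alpha, params.beta) for d in dataset.diseases.ids]
    )
    p_inf = stationary_matrix(t, seeds, params.delta, params.tol, params.max_iter)
    return p_inf[net.n_l + net.n_d :, :].T  # (n_diseases, n_mirnas)


def _rank_against_candidates(
    scores: np.ndarray,
    test_pairs: Sequence[tuple[int, int]],
    candidate_mask: np.ndarray,
    *,
    per_disease: bool,
) -> list[tuple[int, int, float, float, int]]:
    """Midranks of the test pairs among the candidate (unlabeled) pairs."""
    out = []
    for d, m in test_pairs:
        mask = candidate_mask[d, :] if per_disease else candidate_mask
        cand = scores[d, :][mask] if per_disease else scores[mask]
        s = scores[d, m]
        n = int(cand.size)
        rank = 1.0 + float((cand > s).sum()) + 0.5 * float((cand == s).sum())
        out.append((d, m, float(s), rank, n))
    return out


def _run_folds(
    dataset: Dataset,
    params: Params,
    folds: Sequence[Sequence[tuple[int, int]]],
    *,
    recompute_kernels: bool,
    per_disease_candidates: bool,
) -> tuple[list[RankRecord], list[tuple[str, str]], list[list[float]], list[list[int]]]:
    """Mask each fold, rescore, and rank its hidden pairs.

    Candidates are the pairs unlabeled in the *full* data, so every fold's
    hidden pairs are ranked against the same background.
    """
    candidate_mask = dataset.mda.values == 0
    sims = None if recompute_kernels else build_similarities(dataset, params)
    records: list[RankRecord] = []
    failed: list[tuple[str, str]] = []
    fold_ranks: list[list[float]] = []
    fold_ns: list[list[int]] = []
    for fold in folds:
        masked = dataset.with_mda(_mask_pairs(dataset.mda, fold))
        try:
            scores = _score_all(masked, params, sims)
        except ConvergenceError as err:
            for d, m in fold:
                failed.append((dataset.diseases.ids[d], dataset.mirnas.ids[m]))
            logger.warning("fold %s failed to converge (%s); excluded", fold, err)
            continue
        ranked = _rank_against_candidates(
            scores, fold, candidate_mask, per_disease=per_disease_candidates
        )
        fold_ranks.append([r for *_, r, _ in ranked])
        fold_ns.append([n for *_, n in ranked])
        for d, m, s, r, n in ranked:
            records.append(RankRecord(dataset.diseases.ids[d], dataset.mirnas.ids[m], s, r, n))
    return records, failed, fold_ranks, fold_ns


def loocv(
    dataset: Dataset,
    params: Params = Params(),
    *,
    recompute_kernels: bool = True,
    per_disease_candidates: bool = False,
) -> CVResult:
    """Leave-one-out cross-validation over the known associations.

    One fold per known (disease, miRNA) pair: the pair is hidden, the
    kernels and transition matrix rebuilt (``recompute_kernels=False``
    reuses the full-data similarities for speed), and the hidden pair
    ranked among all unlabeled pairs.
    """
    known = list(zip(*np.nonzero(dataset.mda.values)))
    if len(known) < 2:
        raise ParameterError("LOOCV needs at least 2 known associations")
    records, failed, *_ = _run_folds(
        dataset,
        params,
        [[pair] for pair in known],
        recompute_kernels=recompute_kernels,
        per_disease_candidates=per_disease_candidates,
    )
    auc, _ = roc_auc([r.rank for r in records], [r.n_candidates for r in records])
    logger.info("LOOCV: %d folds, AUC %.4f (%d failed)", len(records), auc, len(failed))
    return CVResult("LOOCV", auc, records, failed_folds=failed)


def kfold_cv(
    dataset: Dataset,
    params: Params = Params(),
    k: int = 5,
    reps: int = 100,
    seed: int = 0,
    *,
    recompute_kernels: bool = True,
    per_disease_candidates: bool = False,
) -> CVResult:
    """Repeated k-fold cross-validation over the known associations.

    Known pairs are randomly partitioned into ``k`` folds (one RNG stream
    from ``seed``, so equal seeds give bit-identical results); each fold is
    hidden as a block and its pairs ranked as in LOOCV.  Reports the mean
    AUC with its standard deviation across repetitions, and across folds.
    """
    known = list(zip(*np.nonzero(dataset.mda.values)))
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > len(known):
        raise ParameterError(f"k={k} exceeds the {len(known)} known associations")
    rng = np.random.default_rng(seed)
    all_records: list[RankRecord] = []
    all_failed: list[tuple[str, str]] = []
    rep_aucs: list[float] = []
    per_fold_aucs: list[float] = []
    for _ in range(reps):
        order = rng.permutation(len(known))
        folds = [[known[i] for i in chunk] for chunk in np.array_split(order, k)]
        records, failed, fold_ranks, fold_ns = _run_folds(
            dataset,
            params,
            folds,
            recompute_kernels=recompute_kernels,
            per_disease_candidates=per_disease_candidates,
        )
        all_records.extend(records)
        all_failed.extend(failed)
        if records:
            auc, _ = roc_auc([r.rank for r in records], [r.n_candidates for r in records])
            rep_aucs.append(auc)
        for ranks, ns in zip(fold_ranks, fold_ns):
            if ranks:
                fa, _ = roc_auc(ranks, ns)
                per_fold_aucs.append(fa)
    if not rep_aucs:
        raise ParameterError("all folds failed; no AUC available")
    auc = float(np.mean(rep_aucs))
    logger.info(
        "%d-fold CV x %d reps: AUC %.4f +/- %.4f", k, reps, auc,
        float(np.std(rep_aucs)) if len(rep_aucs) > 1 else 0.0,
    )
    return CVResult(
        "k-fold",
        auc,
        all_records,
        k=k,
        reps=reps,
        seed=seed,
        rep_aucs=rep_aucs,
        auc_sd=float(np.std(rep_aucs, ddof=1)) if len(rep_aucs) > 1 else 0.0,
        auc_sd_folds=float(np.std(per_fold_aucs, ddof=1)) if len(per_fold_aucs) > 1 else 0.0,
        failed_folds=all_failed,
    )


def new_disease_ranks(
    dataset: Dataset,
    disease: str,
    params: Params = Params(),
    *,
    recompute_kernels: bool = True,
) -> list[RankRecord]:
    """Hidden-association protocol for one disease: remove all of its known
    miRNA associations, rebuild, and rank each hidden miRNA among that
    disease's candidates.

    The walk is then seeded only through the disease's lncRNA associations
    and its similarity to other diseases, which is the new-disease setting.
    Returns one record per hidden miRNA (rank within the disease's full
    candidate list).
    """
    d = dataset.diseases.index(disease)
    hidden = [(d, m) for m in np.nonzero(dataset.mda.values[d, :])[0]]
    if not hidden:
        raise ParameterError(f"disease {disease!r} has no known miRNA associations to hide")
    masked = dataset.with_mda(_mask_pairs(dataset.mda, hidden))
    sims = None if recompute_kernels else build_similarities(dataset, params)
    scores = _score_all(masked, params, sims)
    # every miRNA is a candidate for the masked disease; rank each hidden
    # one among the others
    records = []
    for _, m in hidden:
        others = np.delete(scores[d, :], m)
        s = scores[d, m]
        rank = 1.0 + float((others > s).sum()) + 0.5 * float((others == s).sum())
        records.append(
            RankRecord(disease, dataset.mirnas.ids[m], float(s), rank, int(others.size))
        )
    return records
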