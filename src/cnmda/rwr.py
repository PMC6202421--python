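"""Random walk with restart on the composite transition matrix.

The walk iterates ``P(t+1) = (1 - delta) * M^T P(t) + delta * P0`` until the
L1 difference of consecutive iterates falls below a tolerance.  The
transpose convention keeps total probability conserved for a row-stochastic
M (each node pushes its mass along its out-probabilities).  Because the map
is a contraction with factor (1 - delta), the residual shrinks geometrically
and at the default delta = 0.7, tol = 1e-6 convergence takes at most 13
iterations on any network.

Seeds are disease-centric: the disease block is an indicator on the query
disease, the lncRNA and miRNA blocks are uniform over that disease's known
lncRNA / miRNA associates, and the three blocks are weighted alpha, beta and
1 - alpha - beta.  A block with no associates hands its weight to the
remaining blocks proportionally, which is what makes prediction possible
for diseases with no known miRNA at all (new-disease mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .composite import CompositeTransition
from .types import CnmdaError, Dataset, ParameterError

__all__ = [
    "RWRState",
    "RankedPredictions",
    "ConvergenceError",
    "build_seed",
    "rwr_iterate",
    "rwr_closed_form",
    "stationary_matrix",
    "rank_mirnas",
]

logger = logging.getLogger(__name__)


class ConvergenceError(CnmdaError):
    """The walk failed to reach the tolerance within the iteration cap."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


@dataclass
class RWRState:
    """Converged state of one restart walk."""

    p0: np.ndarray
    p_inf: np.ndarray
    delta: float
    alpha: float
    beta: float
    iterations: int
    residual: float
    n_l: int
    n_d: int
    n_m: int

    @property
    def lncrna_scores(self) -> np.ndarray:
        return self.p_inf[: self.n_l]

    @property
    def disease_scores(self) -> np.ndarray:
        return self.p_inf[self.n_l : self.n_l + self.n_d]

    @property
    def mirna_scores(self) -> np.ndarray:
        """w_inf — the block the candidate ranking is read from."""
        return self.p_inf[self.n_l + self.n_d :]


@dataclass
class RankedPredictions:
    """Candidate miRNAs for one disease, sorted by stationary score."""

    disease: str
    entries: list[tuple[str, float, int]]  # (miRNA, score, rank)
    excluded: frozenset[str] = field(default_factory=frozenset)


def build_seed(
    query_disease: str,
    dataset: Dataset,
    alpha: float = 1.0 / 3.0,
    beta: float = 1.0 / 3.0,
) -> np.ndarray:
    """Restart distribution for one query disease.

    Blocks in composite order (lncRNA, disease, miRNA): uniform over the
    disease's known lncRNA associates (weight ``alpha``), indicator on the
    disease (weight ``beta``), uniform over its known miRNA associates
    (weight ``1 - alpha - beta``).  Weights of empty blocks are
    redistributed proportionally so the seed always sums to 1.
    """
    if alpha < 0 or beta < 0 or alpha + beta > 1.0 + 1e-12:
        raise ParameterError(f"block weights alpha={alpha}, beta={beta} invalid")
    d = dataset.diseases.index(query_disease)
    n_l, n_d, n_m = len(dataset.lncrnas), len(dataset.diseases), len(dataset.mirnas)

    u0 = dataset.lda.values[d, :].astype(float)
    w0 = dataset.mda.values[d, :].astype(float)
    v0 = np.zeros(n_d)
    v0[d] = 1.0
    blocks = [u0, v0, w0]
    weights = np.array([alpha, beta, 1.0 - alpha - beta])
    nonempty = np.array([b.sum() > 0 for b in blocks])
    if not nonempty[1]:  # cannot happen: v0 is an indicator
        raise AssertionError("disease indicator block empty")
    active = weights * nonempty
    if active.sum() == 0:
        raise ParameterError("all seed mass assigned to empty blocks")
    weights = active / active.sum()
    if weights[0] == 0 and weights[2] == 0 and (alpha > 0 or 1 - alpha - beta > 0):
        logger.warning(
            "disease %r has no lncRNA or miRNA associations; seeding on the disease node only",
            query_disease,
        )
    parts = []
    for b, w in zip(blocks, weights):
        s = b.sum()
        parts.append(w * b / s if s > 0 else np.zeros_like(b))
    p0 = np.concatenate(parts)
    assert abs(p0.sum() - 1.0) < 1e-9
    return p0


def _check_p0(t: CompositeTransition, p0: np.ndarray) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float)
    if p0.shape[0] != t.matrix.shape[0]:
        raise ParameterError("seed vector length does not match network size")
    if (p0 < 0).any() or not np.allclose(p0.sum(axis=0), 1.0, atol=1e-9):
        raise ParameterError("seed columns must be probability distributions")
    return p0


def rwr_iterate(
    t: CompositeTransition,
    p0: np.ndarray,
    delta: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 1000,
    alpha: float = 1.0 / 3.0,
    beta: float = 1.0 / 3.0,
) -> RWRState:
    """Run the restart walk to its stationary distribution.

    Stops when ``||P(t+1) - P(t)||_1 < tol``; raises
    :class:`ConvergenceError` if ``max_iter`` steps do not suffice.
    """
    if not (0.0 < delta <= 1.0):
        raise ParameterError(f"restart probability delta={delta} outside (0, 1]")
    if tol <= 0:
        raise ParameterError("tol must be positive")
    p0 = _check_p0(t, p0)
    mt = t.matrix.T
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - delta) * (mt @ p) + delta * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            logger.debug("RWR converged in %d iterations (residual %.3g)", it, residual)
            return RWRState(p0, p, delta, alpha, beta, it, residual, t.n_l, t.n_d, t.n_m)
    raise ConvergenceError(
        f"RWR did not reach tol={tol:g} within {max_iter} iterations "
        f"(last residual {residual:.3g})",
        residual,
        max_iter,
    )


def rwr_closed_form(t: CompositeTransition, p0: np.ndarray, delta: float = 0.7) -> np.ndarray:
    """Stationary distribution by direct linear solve of
    ``(I - (1 - delta) M^T) P = delta P0``.

    Exact fixed point of the iteration; intended as an oracle and for small
    networks (dense O(n^3) solve).
    """
    if not (0.0 < delta <= 1.0):
        raise ParameterError(f"restart probability delta={delta} outside (0, 1]")
    p0 = _check_p0(t, p0)
    n = t.matrix.shape[0]
    a = np.eye(n) - (1.0 - delta) * t.matrix.T
    return np.linalg.solve(a, delta * p0)


def stationary_matrix(
    t: CompositeTransition,
    p0s: np.ndarray,
    delta: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Stationary distributions for many seeds at once (columns of ``p0s``);
    iterates all walks jointly until every column's L1 residual is below
    ``tol``.  Used by the cross-validation harness."""
    p0s = _check_p0(t, p0s)
    mt = t.matrix.T
    p = p0s.copy()
    for _ in range(max_iter):
        p_next = (1.0 - delta) * (mt @ p) + delta * p0s
        residual = float(np.abs(p_next - p).sum(axis=0).max())
        p = p_next
        if residual < tol:
            return p
    raise ConvergenceError(
        f"batched RWR did not reach tol={tol:g} within {max_iter} iterations",
        residual,
        max_iter,
    )


def rank_mirnas(
    state: RWRState,
    dataset: Dataset,
    query_disease: str,
    exclude_known: bool = True,
) -> RankedPredictions:
    """Rank candidate miRNAs for the query disease by stationary score.

    Known associates are dropped when ``exclude_known`` (the usual novel-
    prediction setting); exact score ties break by miRNA id so rankings are
    deterministic.
    """
    d = dataset.diseases.index(query_disease)
    scores = state.mirna_scores
    known = {
        dataset.mirnas.ids[j] for j in np.nonzero(dataset.mda.values[d, :])[0]
    } if exclude_known else set()
    candidates = [
        (dataset.mirnas.ids[j], float(scores[j]))
        for j in range(len(dataset.mirnas))
        if dataset.mirnas.ids[j] not in known
    ]
    candidates.sort(key=lambda e: (-e[1], e[0]))
    entries = [(m, s, r) for r, (m, s) in enumerate(candidates, start=1)]
    return RankedPredictions(query_disease, entries, frozenset(known))
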