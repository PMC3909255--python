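"""Propagation scoring of genes against a query disease.

For a query disease *d*, every gene starts with initial information
``Y_g = 1`` if it is associated with *d* and 0 otherwise.  Scores are then
spread over the resource-allocation weighted gene projection ``W`` by the
iteration

    F_t = alpha * W @ F_{t-1} + (1 - alpha) * Y,      F_0 = Y,

where ``alpha`` in (0, 1) balances network information against a gene's own
initial information.  The iteration is a contraction (column sums of ``W``
are ≤ 1, so the spectral radius of ``alpha*W`` is < 1) and converges to

    F = (1 - alpha) * (I - alpha * W)^{-1} @ Y,

available directly through :func:`propagate_closed_form` as an oracle for
the iterative path.  Genes *not* associated with the disease are ranked by
their final score; the top fraction (default 1%) or top *k* (default 10)
become the predicted associations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .network import BipartiteAssociationNetwork
from .projection import ProjectionWeights, resource_allocation_weights

__all__ = [
    "PropagationConfig",
    "ScoreVector",
    "initial_information",
    "propagate",
    "propagate_closed_form",
    "score_disease",
    "rank_candidates",
    "predict_top_fraction",
    "predict_top_k",
]

#: Supported convergence statistics for the iteration.
DEVIATION_STATISTICS = ("mean_square", "max_abs")


@dataclass(frozen=True)
class PropagationConfig:
    """Parameters of the propagation iteration.

    alpha
        Relative weight of network information versus initial information;
        default 0.618 (tuned by cross-validation in the original study).
        ``alpha=0`` is admitted as the degenerate limit in which the scores
        reduce to the initial information after one iteration.
    tol
        Stopping threshold on the deviation between consecutive score
        vectors; default 1e-5.
    max_iter
        Hard iteration cap (the iteration provably converges; the cap is a
        safeguard against misconfigured inputs).
    deviation
        Stopping statistic: ``"mean_square"`` (mean of squared per-gene
        changes, the default) or ``"max_abs"`` (largest absolute per-gene
        change; with this statistic the distance to the fixed point is
        bounded by ``tol * alpha / (1 - alpha)``).
    """

    alpha: float = 0.618
    tol: float = 1e-5
    max_iter: int = 1000
    deviation: str = "mean_square"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")
        if self.deviation not in DEVIATION_STATISTICS:
            raise ValueError(
                f"deviation must be one of {DEVIATION_STATISTICS}, got {self.deviation!r}"
            )


@dataclass
class ScoreVector:
    """Per-gene scores for one query disease.

    ``Y`` is the 0/1 initial-information vector, ``F`` the final scores
    (``None`` until propagation has run).  ``deviations`` records the
    stopping statistic at every iteration.
    """

    gene_order: tuple[str, ...]
    Y: np.ndarray
    F: np.ndarray | None = None
    disease_id: str | None = None
    iterations_used: int = 0
    converged: bool = False
    deviations: tuple[float, ...] = field(default=(), repr=False)


def initial_information(net: BipartiteAssociationNetwork, disease: str) -> ScoreVector:
    """Build the 0/1 initial-information vector for a query disease.

    ``Y_g = 1`` iff the association (g, disease) is present.  A degree-0
    disease (possible before pruning) yields an all-zero vector and a
    warning — propagation then returns all-zero scores.
    """
    if not net.has_disease(disease):
        raise KeyError(f"disease {disease!r} not in network")
    A, gene_order, disease_order = net.adjacency()
    Y = A[:, disease_order.index(disease)].astype(float)
    if Y.sum() == 0:
        warnings.warn(
            f"disease {disease!r} has no associated genes; initial information is all zero",
            stacklevel=2,
        )
    return ScoreVector(gene_order=gene_order, Y=Y, disease_id=disease)


def _matrix_of(weights: ProjectionWeights | np.ndarray | sparse.csr_array):
    return weights.matrix if isinstance(weights, ProjectionWeights) else weights


def _check_finite(M, Y: np.ndarray) -> None:
    data = M.data if sparse.issparse(M) else np.asarray(M)
    if not np.all(np.isfinite(data)):
        raise ValueError("weight matrix contains non-finite values")
    if not np.all(np.isfinite(Y)):
        raise ValueError("initial information vector contains non-finite values")


def _propagate_arrays(M, Y: np.ndarray, cfg: PropagationConfig):
    """Core iteration on raw arrays; returns (F, iterations, converged, devs)."""
    Y = np.asarray(Y, dtype=float)
    F = Y.copy()
    devs: list[float] = []
    one_minus = (1.0 - cfg.alpha) * Y
    for t in range(1, cfg.max_iter + 1):
        F_next = cfg.alpha * (M @ F) + one_minus
        diff = F_next - F
        if diff.size == 0:
            dev = 0.0
        elif cfg.deviation == "mean_square":
            dev = float(np.mean(diff * diff))
        else:
            dev = float(np.max(np.abs(diff)))
        devs.append(dev)
        F = F_next
        if dev <= cfg.tol:
            return F, t, True, devs
    return F, cfg.max_iter, False, devs


def propagate(
    weights: ProjectionWeights, Y: np.ndarray, cfg: PropagationConfig | None = None
) -> ScoreVector:
    """Run the propagation iteration from ``F_0 = Y`` until convergence.

    ``Y`` must be indexed by ``weights.gene_order``.  Stops when the
    configured deviation statistic between consecutive score vectors drops
    to ``cfg.tol`` or below, or after ``cfg.max_iter`` iterations
    (``converged=False`` in that case).
    """
    cfg = cfg or PropagationConfig()
    M = _matrix_of(weights)
    Y = np.asarray(Y, dtype=float)
    gene_order = (
        weights.gene_order
        if isinstance(weights, ProjectionWeights)
        else tuple(str(i) for i in range(len(Y)))
    )
    if Y.shape != (len(gene_order),):
        raise ValueError(f"Y must have shape ({len(gene_order)},), got {Y.shape}")
    _check_finite(M, Y)
    F, iters, converged, devs = _propagate_arrays(M, Y, cfg)
    return ScoreVector(
        gene_order=gene_order,
        Y=Y,
        F=F,
        iterations_used=iters,
        converged=converged,
        deviations=tuple(devs),
    )


def propagate_closed_form(
    weights: ProjectionWeights | np.ndarray, Y: np.ndarray, alpha: float
) -> np.ndarray:
    """Solve the propagation fixed point directly.

    Computes ``F = (1 - alpha) * (I - alpha*W)^{-1} Y`` by a linear solve.
    Valid for ``alpha`` in (0, 1): column sums of ``W`` are ≤ 1, so
    ``I - alpha*W`` is nonsingular.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    M = _matrix_of(weights)
    Y = np.asarray(Y, dtype=float)
    _check_finite(M, Y)
    n = Y.shape[0]
    if sparse.issparse(M):
        system = sparse.eye_array(n, format="csc") - alpha * M.tocsc()
        return spsolve(system, (1.0 - alpha) * Y)
    return np.linalg.solve(np.eye(n) - alpha * np.asarray(M), (1.0 - alpha) * Y)


def score_disease(
    net: BipartiteAssociationNetwork,
    disease: str,
    cfg: PropagationConfig | None = None,
    weights: ProjectionWeights | None = None,
) -> ScoreVector:
    """Convenience: initial information + propagation for one disease.

    ``weights`` may be passed to reuse a precomputed matrix; it must share
    the network's gene order.
    """
    cfg = cfg or PropagationConfig()
    sv = initial_information(net, disease)
    if weights is None:
        weights = resource_allocation_weights(net)
    if weights.gene_order != sv.gene_order:
        raise ValueError("weights gene order does not match network gene order")
    result = propagate(weights, sv.Y, cfg)
    result.disease_id = disease
    return result


def rank_candidates(
    scores: ScoreVector, net: BipartiteAssociationNetwork
) -> list[tuple[str, float, int]]:
    """Rank genes *not* associated with the query disease by final score.

    Returns ``(gene_id, score, rank)`` triples with dense 1-based ranks,
    descending by score.  Ties break by ascending gene id — ranks define
    predictions, so the tie rule is deterministic by design.
    """
    if scores.F is None:
        raise ValueError("scores have not been propagated yet (F is None)")
    if scores.disease_id is None:
        raise ValueError("scores are not tied to a query disease")
    associated = set(net.disease_neighbors[scores.disease_id])
    candidates = [
        (gid, float(scores.F[i]))
        for i, gid in enumerate(scores.gene_order)
        if gid not in associated
    ]
    # gene_order is sorted, so a stable sort on -score breaks ties by id
    candidates.sort(key=lambda item: -item[1])
    return [(gid, score, rank) for rank, (gid, score) in enumerate(candidates, start=1)]


def predict_top_fraction(
    ranked: list[tuple[str, float, int]], fraction: float = 0.01
) -> list[tuple[str, float, int]]:
    """Top ``ceil(fraction * n)`` candidates (at least one when non-empty)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if not ranked:
        return []
    n_keep = max(1, math.ceil(fraction * len(ranked)))
    return list(ranked[:n_keep])


def predict_top_k(
    ranked: list[tuple[str, float, int]], k: int = 10
) -> list[tuple[str, float, int]]:
    """First ``min(k, n)`` candidates."""
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    return list(ranked[:k])
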