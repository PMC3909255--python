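"""Degree-preserving randomization, resampling robustness and z-tests.

Three null/robustness tools accompany the predictor:

* :func:`degree_preserving_shuffle` — repeated double edge swaps on the
  bipartite network, keeping every gene's and every disease's degree fixed
  (the standard configuration-model null for association networks);
* :func:`mss_robustness` — Multiple-Survival-Screening style resampling:
  drop a fraction of edges repeatedly and count, for each association
  predicted from the full network, how often it is re-predicted (``R``); the
  same count over degree-preserving shuffles (``R_r``) calibrates chance;
* :func:`ensemble_ztest` — a plain z-statistic of an observed value against
  a null ensemble, used for the topology comparisons as well.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import BipartiteAssociationNetwork
from .projection import OneModeProjection, _weights_from_adjacency
from .propagation import PropagationConfig, _propagate_arrays

__all__ = [
    "ShuffleConfig",
    "RobustnessResult",
    "ZTestResult",
    "degree_preserving_shuffle",
    "mss_robustness",
    "ensemble_ztest",
    "same_class_link_count",
]


@dataclass(frozen=True)
class ShuffleConfig:
    """Seed and swap budget for degree-preserving shuffling.

    ``n_swaps=None`` defaults to 10 × |edges| attempted double edge swaps, a
    standard mixing heuristic.
    """

    seed: int = 0
    n_swaps: int | None = None

    def __post_init__(self) -> None:
        if self.n_swaps is not None and self.n_swaps < 0:
            raise ValueError("n_swaps must be >= 0")


def degree_preserving_shuffle(
    net: BipartiteAssociationNetwork, cfg: ShuffleConfig | int = ShuffleConfig()
) -> BipartiteAssociationNetwork:
    """Shuffle associations while preserving both degree sequences.

    Repeatedly picks two edges (g1,d1), (g2,d2) and rewires them to
    (g1,d2), (g2,d1); swaps that would duplicate an existing edge or touch a
    shared endpoint are rejected, so the result is a simple bipartite graph
    with every node's degree unchanged.  Networks admitting no legal swap
    (e.g. complete bipartite) come back as copies.

    ``cfg`` may be a :class:`ShuffleConfig` or a bare integer seed.
    """
    if isinstance(cfg, int):
        cfg = ShuffleConfig(seed=cfg)
    edges = sorted(net.edges)
    if len(edges) < 2 or cfg.n_swaps == 0:
        return net.with_edges(edges)
    n_swaps = cfg.n_swaps if cfg.n_swaps is not None else 10 * len(edges)
    rng = np.random.default_rng(cfg.seed)
    edge_set = set(edges)
    for _ in range(n_swaps):
        a, b = rng.integers(0, len(edges), size=2)
        if a == b:
            continue
        g1, d1 = edges[a]
        g2, d2 = edges[b]
        if g1 == g2 or d1 == d2:
            continue
        if (g1, d2) in edge_set or (g2, d1) in edge_set:
            continue
        edge_set.discard((g1, d1))
        edge_set.discard((g2, d2))
        edge_set.add((g1, d2))
        edge_set.add((g2, d1))
        edges[a] = (g1, d2)
        edges[b] = (g2, d1)
    return net.with_edges(edge_set)


def _predict_all(
    net: BipartiteAssociationNetwork, cfg: PropagationConfig, fraction: float
) -> list[tuple[str, str]]:
    """Top-fraction predicted (gene, disease) pairs for every scorable disease.

    Diseases without any remaining association are skipped (their initial
    information is all zero, so no gene can receive a score).
    """
    A, genes, diseases = net.adjacency()
    W = _weights_from_adjacency(A)
    predictions: list[tuple[str, str]] = []
    for j, d in enumerate(diseases):
        y = A[:, j]
        if y.sum() == 0:
            continue
        F, *_ = _propagate_arrays(W, y, cfg)
        cand = np.flatnonzero(y == 0)
        if cand.size == 0:
            continue
        order = cand[np.argsort(-F[cand], kind="stable")]
        n_keep = max(1, math.ceil(fraction * cand.size))
        predictions.extend((genes[i], d) for i in order[:n_keep])
    return predictions


@dataclass(frozen=True)
class RobustnessResult:
    """Recurrence of full-network predictions under resampling vs shuffling.

    ``R[i]`` counts in how many of the ``n_resample`` edge-dropped replicas
    prediction ``predictions[i]`` was re-predicted; ``R_r[i]`` counts the
    same over degree-preserving shuffles.  ``z`` is the two-sample
    z-statistic of ``R`` against ``R_r`` (sample standard deviations).
    """

    predictions: tuple[tuple[str, str], ...]
    R: np.ndarray = field(repr=False)
    R_r: np.ndarray = field(repr=False)
    n_resample: int
    drop_frac: float
    fraction: float
    z: float

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g for g, _ in self.predictions],
                "disease_id": [d for _, d in self.predictions],
                "R": self.R,
                "n_resample": self.n_resample,
                "R_random": self.R_r,
            }
        )


def _two_sample_z(x: np.ndarray, y: np.ndarray) -> float:
    sx = x.std(ddof=1) if x.size > 1 else 0.0
    sy = y.std(ddof=1) if y.size > 1 else 0.0
    denom = math.sqrt(sx**2 / max(x.size, 1) + sy**2 / max(y.size, 1))
    if denom == 0.0:
        return float("nan")
    return float((x.mean() - y.mean()) / denom)


def mss_robustness(
    net: BipartiteAssociationNetwork,
    cfg: PropagationConfig | None = None,
    *,
    n_resample: int = 100,
    drop_frac: float = 0.10,
    fraction: float = 0.01,
    seed: int = 0,
) -> RobustnessResult:
    """Resampling robustness of the full-network predictions.

    The prediction set is fixed once from the full network (top-``fraction``
    rule per disease).  Each of ``n_resample`` replicas drops
    ``floor(drop_frac * |E|)`` uniformly chosen edges, re-runs prediction on
    the remainder (thresholds recomputed on the reduced candidate pools) and
    increments ``R`` for every full-network prediction that recurs.  ``R_r``
    is computed identically on degree-preserving shuffles of the full
    network.
    """
    if not 0.0 < drop_frac < 1.0:
        raise ValueError(f"drop_frac must lie in (0, 1), got {drop_frac}")
    if n_resample < 1:
        raise ValueError("n_resample must be >= 1")
    cfg = cfg or PropagationConfig()
    predictions = _predict_all(net, cfg, fraction)
    pred_index = {p: i for i, p in enumerate(predictions)}
    R = np.zeros(len(predictions), dtype=int)
    R_r = np.zeros(len(predictions), dtype=int)
    rng = np.random.default_rng(seed)
    edges = sorted(net.edges)
    n_drop = int(drop_frac * len(edges))

    for _ in range(n_resample):
        dropped = set(rng.choice(len(edges), size=n_drop, replace=False).tolist())
        kept = [e for i, e in enumerate(edges) if i not in dropped]
        reduced = net.with_edges(kept)
        for pair in _predict_all(reduced, cfg, fraction):
            i = pred_index.get(pair)
            if i is not None:
                R[i] += 1

    for _ in range(n_resample):
        shuffled = degree_preserving_shuffle(
            net, ShuffleConfig(seed=int(rng.integers(2**31)))
        )
        for pair in _predict_all(shuffled, cfg, fraction):
            i = pred_index.get(pair)
            if i is not None:
                R_r[i] += 1

    return RobustnessResult(
        predictions=tuple(predictions),
        R=R,
        R_r=R_r,
        n_resample=n_resample,
        drop_frac=drop_frac,
        fraction=fraction,
        z=_two_sample_z(R.astype(float), R_r.astype(float)),
    )


@dataclass(frozen=True)
class ZTestResult:
    """Observed value against a null ensemble: z = (obs − mean) / sd."""

    observed: float
    null_mean: float
    null_sd: float
    z: float


def ensemble_ztest(observed: float, null_samples: Sequence[float]) -> ZTestResult:
    """z-statistic of ``observed`` against ``null_samples`` (sample sd, n−1)."""
    samples = np.asarray(list(null_samples), dtype=float)
    if samples.size < 2:
        raise ValueError("need at least two null samples")
    sd = float(samples.std(ddof=1))
    if sd == 0.0:
        raise ValueError("null ensemble has zero variance; z-statistic undefined")
    mean = float(samples.mean())
    return ZTestResult(
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        z=(float(observed) - mean) / sd,
    )


def same_class_link_count(
    proj: OneModeProjection, classes: Mapping[str, str | None]
) -> int:
    """Number of projection edges whose endpoints share a class label.

    Nodes without a class label are excluded (with a warning), matching the
    enrichment question "are same-class diseases linked more often than in
    degree-matched random networks?".
    """
    unlabeled = [n for n in proj.nodes if classes.get(n) is None]
    if unlabeled:
        warnings.warn(
            f"{len(unlabeled)} projection node(s) lack a class label and are excluded",
            stacklevel=2,
        )
    count = 0
    for u, v in proj.shared_count:
        cu, cv = classes.get(u), classes.get(v)
        if cu is not None and cu == cv:
            count += 1
    return count
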