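"""Descriptive network statistics for projections and bipartite networks.

Degree histograms with a log-log slope summary, Watts-Strogatz clustering
coefficients, giant-component sizes, and z-test comparisons against
degree-sequence-preserving random ensembles.  Graph algorithms delegate to
networkx; the randomized null uses double edge swaps, which guarantees
simple graphs with exactly the input degree sequence.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import BipartiteAssociationNetwork
from .projection import OneModeProjection
from .randomization import ZTestResult, ensemble_ztest

__all__ = [
    "TopologySummary",
    "ClusteringResult",
    "degree_distribution",
    "clustering_coefficient",
    "giant_component_size",
    "topology_vs_random",
    "summarize_projection",
]

STATISTICS = ("giant_component", "avg_clustering")


@dataclass(frozen=True)
class TopologySummary:
    """Descriptive statistics of one graph (fields absent where not computed)."""

    n_nodes: int
    degree_histogram: dict[int, int]
    loglog_slope: float
    avg_clustering: float | None = None
    clustering_by_degree: dict[int, float] | None = None
    giant_component_size: int | None = None


@dataclass(frozen=True)
class ClusteringResult:
    per_node: dict[str, float]
    average: float


def _as_graph(obj) -> nx.Graph:
    if isinstance(obj, OneModeProjection):
        return obj.to_networkx()
    if isinstance(obj, nx.Graph):
        return obj
    raise TypeError(f"expected OneModeProjection or networkx.Graph, got {type(obj)!r}")


def _degrees_of(graph, side: str | None) -> list[int]:
    if isinstance(graph, BipartiteAssociationNetwork):
        g_deg = list(graph.gene_degrees.values())
        d_deg = list(graph.disease_degrees.values())
        if side in (None, "both"):
            return g_deg + d_deg
        if side == "gene":
            return g_deg
        if side == "disease":
            return d_deg
        raise ValueError(f"side must be 'gene', 'disease' or 'both', got {side!r}")
    if side is not None:
        raise ValueError("side applies only to bipartite networks")
    G = _as_graph(graph)
    return [d for _, d in G.degree()]


def _loglog_slope(degrees: np.ndarray, n_nodes: int) -> float:
    """Least-squares slope of log10 P(k) vs log10 k on log-binned degrees ≥ 1.

    Bins are powers of two; the per-bin density is the node fraction in the
    bin divided by bin width, placed at the geometric bin center.  Returns
    NaN when fewer than two bins are occupied.
    """
    degrees = degrees[degrees >= 1]
    if degrees.size == 0:
        return float("nan")
    k_max = int(degrees.max())
    n_bins = max(1, int(np.ceil(np.log2(k_max + 1))))
    edges = 2.0 ** np.arange(0, n_bins + 1)
    counts, _ = np.histogram(degrees, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    density = counts / n_nodes / widths
    occupied = density > 0
    if occupied.sum() < 2:
        return float("nan")
    slope, _ = np.polyfit(np.log10(centers[occupied]), np.log10(density[occupied]), 1)
    return float(slope)


def degree_distribution(graph, side: str | None = None) -> TopologySummary:
    """Exact degree histogram plus a descriptive log-log slope.

    ``graph`` is a projection, a networkx graph, or a bipartite network (in
    which case ``side`` selects ``"gene"``, ``"disease"`` or ``"both"``
    degrees).  A clearly negative slope is the package's descriptive summary
    of a heavy-tailed (power-law-like) distribution; no maximum-likelihood
    exponent is fitted.
    """
    degrees = _degrees_of(graph, side)
    if not degrees:
        raise ValueError("graph has no nodes")
    histogram = dict(sorted(Counter(degrees).items()))
    slope = _loglog_slope(np.asarray(degrees), len(degrees))
    return TopologySummary(
        n_nodes=len(degrees), degree_histogram=histogram, loglog_slope=slope
    )


def clustering_coefficient(graph, *, include_low_degree: bool = True) -> ClusteringResult:
    """Watts-Strogatz local clustering per node and its network average.

    Nodes of degree < 2 have no closed triples and contribute 0; by default
    they are included in the average (``include_low_degree=False`` averages
    over nodes of degree ≥ 2 only).
    """
    G = _as_graph(graph)
    local = nx.clustering(G)
    per_node = {str(n): float(c) for n, c in local.items()}
    if include_low_degree:
        pool = list(per_node.values())
    else:
        pool = [per_node[str(n)] for n, d in G.degree() if d >= 2]
    average = float(np.mean(pool)) if pool else 0.0
    return ClusteringResult(per_node=per_node, average=average)


def giant_component_size(graph) -> int:
    """Number of nodes in the largest connected component (0 when empty)."""
    G = _as_graph(graph)
    if G.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(G))


def _null_statistic(H: nx.Graph, statistic: str) -> float:
    if statistic == "giant_component":
        return float(giant_component_size(H))
    return clustering_coefficient(H).average


def topology_vs_random(
    proj,
    statistic: str,
    n_random: int = 100,
    seed: int = 0,
    n_swaps: int | None = None,
) -> ZTestResult:
    """z-test of a projection statistic against a degree-matched ensemble.

    The null ensemble applies double edge swaps to the projection itself
    (``n_swaps=None`` → 10 × |edges| swaps), preserving the degree sequence
    exactly while randomizing which nodes connect.  Supported statistics:
    ``"giant_component"`` and ``"avg_clustering"``.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}, got {statistic!r}")
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    G = _as_graph(proj)
    observed = _null_statistic(G, statistic)
    reference_degrees = sorted(d for _, d in G.degree())
    budget = n_swaps if n_swaps is not None else 10 * G.number_of_edges()
    rng = np.random.default_rng(seed)
    samples: list[float] = []
    for _ in range(n_random):
        H = G.copy()
        if budget > 0 and H.number_of_edges() >= 2:
            try:
                nx.double_edge_swap(
                    H,
                    nswap=budget,
                    max_tries=100 * budget + 100,
                    seed=int(rng.integers(2**31)),
                )
            except nx.NetworkXError:
                pass  # too few legal swaps; keep the (partially) shuffled copy
        if sorted(d for _, d in H.degree()) != reference_degrees:
            raise RuntimeError("null draw changed the degree sequence")
        samples.append(_null_statistic(H, statistic))
    return ensemble_ztest(observed, samples)


def summarize_projection(proj) -> TopologySummary:
    """Full descriptive summary of a one-mode projection."""
    G = _as_graph(proj)
    base = degree_distribution(G)
    clustering = clustering_coefficient(G)
    by_degree: dict[int, list[float]] = defaultdict(list)
    for n, d in G.degree():
        by_degree[int(d)].append(clustering.per_node[str(n)])
    return TopologySummary(
        n_nodes=base.n_nodes,
        degree_histogram=base.degree_histogram,
        loglog_slope=base.loglog_slope,
        avg_clustering=clustering.average,
        clustering_by_degree={k: float(np.mean(v)) for k, v in sorted(by_degree.items())},
        giant_component_size=giant_component_size(G),
    )
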